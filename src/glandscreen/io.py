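"""Readers and writers for the on-disk formats shared by every pipeline stage.

Formats handled here:

* protein FASTA (via :mod:`Bio.SeqIO`),
* alignment hit tables — tab-separated BLAST ``outfmt 6`` rows prefixed with
  one extra column naming the subject organism (13 columns total),
* protein × sample intensity matrices (TSV; empty cells and literal ``0``
  both denote "not detected"),
* microtiter-plate OD600 readings (CSV with columns ``peptide_id, strain,
  concentration_ug_ml, replicate, od600, well_type``),
* a flat key-value run configuration (YAML mapping).

All parsers reject malformed input with a precise error rather than coercing
silently.  Sequence coordinates are 0-based half-open everywhere in memory
and 1-based inclusive in files.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: characters accepted on read; ``X`` (unknown residue) is tolerated but flagged
READ_ALPHABET = frozenset(AMINO_ACIDS + "X")


class FormatError(ValueError):
    """A file violated the format contract of one of the readers."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein database entry (an open reading frame or mature protein)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_unknown_residues(self) -> bool:
        return "X" in self.sequence


@dataclass(frozen=True)
class RunConfig:
    """Flat bundle of the tunable analysis parameters.

    ``confidence_bounds`` are the two E-value thresholds separating the three
    homology-confidence classes; ``evalue_cutoff`` is the transfer cutoff.
    Window sizes bound the sliding-window digestion of the proteome.
    """

    window_min: int = 8
    window_max: int = 15
    evalue_cutoff: float = 1e-20
    confidence_bounds: tuple[float, float] = (1e-20, 1e-5)
    kmeans_k: int = 6
    pca_components: int = 2
    mic_threshold: float = 90.0
    rng_seed: int = 42
    # knobs beyond the headline thresholds, all with documented defaults
    loading_quantile: float = 0.75
    missing_downshift: float = 0.5
    pseaac_lambda: int = 4
    pseaac_weight: float = 0.05
    amp_probability_threshold: float = 0.8

    def __post_init__(self) -> None:
        if self.window_min > self.window_max:
            raise ValueError(
                f"window_min ({self.window_min}) > window_max ({self.window_max})"
            )
        if self.window_min < 1:
            raise ValueError("window_min must be positive")
        lo, hi = self.confidence_bounds
        if not (0 < lo < hi):
            raise ValueError("confidence_bounds must be strictly ordered and positive")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")
        if self.kmeans_k < 1 or self.pca_components < 1:
            raise ValueError("kmeans_k and pca_components must be positive")
        if not (0 < self.mic_threshold <= 100):
            raise ValueError("mic_threshold must lie in (0, 100]")
        if not (0 <= self.loading_quantile <= 1):
            raise ValueError("loading_quantile must lie in [0, 1]")
        if self.pseaac_lambda < 0 or self.pseaac_weight < 0:
            raise ValueError("pseaac_lambda/pseaac_weight must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a flat key-value YAML mapping; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"{path}: config must be a flat key-value mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        if "confidence_bounds" in raw:
            raw["confidence_bounds"] = tuple(float(x) for x in raw["confidence_bounds"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        data["confidence_bounds"] = list(data["confidence_bounds"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def with_(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into a list of :class:`ProteinRecord`.

    Order is preserved and sequences are uppercased.  Duplicate identifiers,
    empty sequences and characters outside the 20-letter alphabet (plus X)
    are hard errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: protein {rec.id!r} has an empty sequence")
        for pos, ch in enumerate(seq, start=1):
            if ch not in READ_ALPHABET:
                raise FormatError(
                    f"{path}: protein {rec.id!r} has illegal character "
                    f"{ch!r} at position {pos}"
                )
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(ProteinRecord(rec.id, seq, desc))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# hit tables (BLAST outfmt 6 + leading organism column)

#: column order of the on-disk hit-table dialect
HIT_COLUMNS = (
    "organism", "query_id", "subject_id", "identity", "align_len",
    "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
    "evalue", "bitscore",
)


def read_hit_table(path: str | Path):
    """Read an alignment hit table into a list of :class:`HitRecord`.

    The dialect is tab-separated BLAST ``outfmt 6`` with one extra leading
    column naming the subject organism (13 columns total), so the best hit
    per organism is recoverable from a single file.
    """
    from .annotation import HitRecord  # local import: avoid a cycle

    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(HIT_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(HIT_COLUMNS)} tab-separated "
                    f"columns, got {len(parts)}"
                )
            row = dict(zip(HIT_COLUMNS, parts))
            try:
                evalue = float(row["evalue"])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: unparseable E-value {row['evalue']!r}"
                ) from None
            if not math.isfinite(evalue) or evalue < 0:
                raise FormatError(f"{path}:{lineno}: negative or non-finite E-value")
            try:
                hits.append(
                    HitRecord(
                        query_id=row["query_id"],
                        subject_id=row["subject_id"],
                        organism=row["organism"],
                        evalue=evalue,
                        identity=float(row["identity"]),
                        bitscore=float(row["bitscore"]),
                        align_len=int(row["align_len"]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return hits


def write_hit_table(hits, path: str | Path) -> None:
    """Write hits in the 13-column dialect; placeholder alignment coordinates.

    Only the fields the analysis consumes (organism, ids, identity, length,
    E-value, bit score) carry information; the remaining ``outfmt 6`` columns
    are emitted as zeros/1-based spans for format compatibility.
    """
    with open(path, "w") as fh:
        for h in hits:
            fields = (
                h.organism, h.query_id, h.subject_id,
                f"{h.identity:g}", str(h.align_len), "0", "0",
                "1", str(h.align_len), "1", str(h.align_len),
                f"{h.evalue:g}", f"{h.bitscore:g}",
            )
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# intensity matrices


def read_intensity_matrix(path: str | Path, roles: Mapping[str, str] | None = None):
    """Read a protein × sample TSV of iBAQ-style intensities.

    First column is the protein id; the remaining columns are samples.  Empty
    cells and literal ``0`` both denote a missing (not-detected) value, the
    convention of MaxQuant-style output where 0 means no peptide evidence.
    """
    from .enrichment import IntensityMatrix  # local import: avoid a cycle

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for name in header:
        if name in seen:
            raise FormatError(f"{path}: repeated sample name {name!r}")
        seen.add(name)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate protein id {dup!r}")
    values = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            cell = cell.strip()
            if cell == "" or cell == "0":
                continue
            try:
                v = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at protein "
                    f"{df.index[i]!r}, sample {col!r}"
                ) from None
            if v == 0.0:
                continue  # "0.0" is the same non-detection convention
            values[i, j] = v
    data = pd.DataFrame(values, index=df.index, columns=df.columns)
    return IntensityMatrix(data=data, roles=dict(roles) if roles else None)


def write_intensity_matrix(matrix, path: str | Path) -> None:
    """Write an intensity matrix as TSV; missing values become empty cells."""
    df = matrix.data
    with open(path, "w") as fh:
        fh.write("protein_id\t" + "\t".join(df.columns) + "\n")
        for pid, row in df.iterrows():
            cells = ["" if not np.isfinite(v) else repr(float(v)) for v in row]
            fh.write(str(pid) + "\t" + "\t".join(cells) + "\n")


def read_roles(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping sample name -> role tag."""
    roles: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'sample<TAB>role'")
            sample, role = parts
            if sample in roles:
                raise FormatError(f"{path}:{lineno}: duplicate sample {sample!r}")
            roles[sample] = role
    return roles


def write_roles(roles: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, role in roles.items():
            fh.write(f"{sample}\t{role}\n")


# ---------------------------------------------------------------------------
# plate CSV

PLATE_COLUMNS = ("peptide_id", "strain", "concentration_ug_ml", "replicate",
                 "od600", "well_type")
WELL_TYPES = {"test", "control", "blank"}


def read_plate_csv(path: str | Path):
    """Read microtiter-plate OD600 readings into :class:`PlateAssay` objects.

    One :class:`PlateAssay` is built per (peptide, strain) pair.  Control and
    blank wells carry no concentration; test wells must.
    """
    from .assay import PlateAssay  # local import: avoid a cycle

    groups: dict[tuple[str, str], dict] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != PLATE_COLUMNS:
            raise FormatError(
                f"{path}: header must be {','.join(PLATE_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            wt = row["well_type"].strip()
            if wt not in WELL_TYPES:
                raise FormatError(f"{path}:{lineno}: unknown well_type {wt!r}")
            try:
                od = float(row["od600"])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric od600") from None
            key = (row["peptide_id"].strip(), row["strain"].strip())
            g = groups.setdefault(key, {"test": {}, "control": [], "blank": []})
            if wt == "test":
                try:
                    conc = float(row["concentration_ug_ml"])
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: test well needs a numeric concentration"
                    ) from None
                if conc <= 0:
                    raise FormatError(f"{path}:{lineno}: non-positive concentration")
                g["test"].setdefault(conc, []).append(od)
            else:
                g[wt].append(od)
    assays = []
    for (pid, strain), g in sorted(groups.items()):
        concs = sorted(g["test"], reverse=True)
        assays.append(
            PlateAssay(
                peptide_id=pid,
                strain=strain,
                concentrations=tuple(concs),
                od_test=tuple(tuple(g["test"][c]) for c in concs),
                od_control=tuple(g["control"]),
                od_blank=tuple(g["blank"]) or None,
            )
        )
    return assays


def write_plate_csv(assays, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PLATE_COLUMNS)
        for a in assays:
            for conc, reps in zip(a.concentrations, a.od_test):
                for i, od in enumerate(reps, start=1):
                    writer.writerow(
                        [a.peptide_id, a.strain, repr(float(conc)), i,
                         repr(float(od)), "test"])
            for i, od in enumerate(a.od_control, start=1):
                writer.writerow([a.peptide_id, a.strain, "", i, repr(float(od)),
                                 "control"])
            for i, od in enumerate(a.od_blank or (), start=1):
                writer.writerow([a.peptide_id, a.strain, "", i, repr(float(od)),
                                 "blank"])
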