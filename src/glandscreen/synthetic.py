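"""Synthetic inputs with the statistical structure the pipeline assumes.

Every file the analysis consumes can be generated here: a proteome of
random-composition proteins, a tissue-panel iBAQ intensity matrix with a
planted gland-enriched cluster, cross-species hit tables with planted
orthology, cationic/amphipathic AMP-like versus background peptide corpora,
and logistic (Hill) dose-response OD600 plates.  All generators are pure
functions of their :class:`SimulationSpec` and seed — identical seeds give
identical bytes — and the planted ground truth is always returned alongside
the data, never embedded in it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import ProteinRecord
from .annotation import HitRecord

#: average Swiss-Prot amino-acid frequencies (fractions, sum to 1)
BACKGROUND_FREQUENCIES = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0672, "G": 0.0707, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0665, "T": 0.0536, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}
_BG_AA = np.array(list(BACKGROUND_FREQUENCIES))
_BG_P = np.array(list(BACKGROUND_FREQUENCIES.values()))
_BG_P = _BG_P / _BG_P.sum()

_HYDROPHOBIC = np.array(list("AILMFVW"))
_POLAR = np.array(list("STNQGDE"))

#: reference-panel organisms for the synthetic hit tables
ORGANISMS = (
    "Alligator_mississippiensis", "Alligator_sinensis", "Iguana_iguana",
    "Conolophus_subcristatus", "Amblyrhynchus_cristatus",
    "Anolis_carolinensis", "Gallus_gallus", "Homo_sapiens",
    "Mus_musculus", "Rattus_norvegicus", "Micrurus_spixii",
)

#: sample panel of the synthetic intensity matrix (name -> role)
def default_sample_roles(n_tissues: int = 5,
                         n_fg_fractions: int = 7) -> dict[str, str]:
    """Femoral-gland secretion as gel fractions, plus the body-fluid panel.

    The gland secretion is separated on a gel and measured fraction by
    fraction (seven fractions in the reference protocol), so it contributes
    several FG-tagged columns; the other fluids and tissues contribute one
    column each.
    """
    tissues = ["brain", "heart", "lung", "muscle", "skin",
               "kidney", "liver", "spleen"][:n_tissues]
    roles = {f"FG_f{i}": "FG" for i in range(1, n_fg_fractions + 1)}
    roles.update({"SF": "SF", "serum": "serum", "erythrocyte": "erythrocyte"})
    roles.update({t: "tissue" for t in tissues})
    return roles


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of every synthetic generator, with validation.

    Defaults describe a desk-scale study: a proteome of ~10^3 proteins, a
    nine-sample tissue panel with 40 proteins planted at 100-fold elevated
    femoral-gland intensity (half the log-effect in seminal fluid) and 10%
    missingness, 200+200 training peptides separable through a charge and
    amphipathy bias, and duplicate Hill-response plates.
    """

    n_proteins: int = 1000
    mean_length: float = 350.0
    sd_length: float = 150.0
    min_length: int = 30
    n_tissues: int = 5
    n_fg_fractions: int = 7
    planted_enriched: int = 40
    enrichment_fold: float = 100.0
    missing_rate: float = 0.1
    baseline_log_mean: float = 7.0
    baseline_log_sd: float = 1.0
    sample_log_sd: float = 0.25
    sample_effect_sd: float = 0.3
    tissue_specific_fraction: float = 0.75
    tissue_effect: float = 1.2
    n_amp: int = 200
    n_background: int = 200
    amp_charge_bias: float = 0.3
    amp_hydropathy_bias: float = 0.5
    hit_fraction: float = 0.965
    dose_ec50: float = 125.0
    dose_hill: float = 2.0
    od_noise_sd: float = 0.02
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_tissues", "n_fg_fractions", "n_amp",
                     "n_background"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("missing_rate", "amp_charge_bias", "amp_hydropathy_bias",
                     "hit_fraction", "tissue_specific_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1 (1 = null effect)")
        if self.planted_enriched < 0:
            raise ValueError("planted_enriched must be non-negative")
        if self.mean_length <= 0 or self.sd_length < 0:
            raise ValueError("length distribution parameters must be positive")
        if self.dose_ec50 <= 0 or self.dose_hill <= 0:
            raise ValueError("dose_ec50 and dose_hill must be positive")
        if self.od_noise_sd < 0:
            raise ValueError("od_noise_sd must be non-negative")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Independent generator for one named sub-stream of the seed."""
        return np.random.default_rng(np.random.SeedSequence(
            entropy=self.seed, spawn_key=(stream,)))


# sub-stream indices, fixed so generators stay independent of call order
_STREAM_PROTEOME = 0
_STREAM_INTENSITY = 1
_STREAM_CORPUS = 2
_STREAM_HITS = 3
_STREAM_PLATE = 4
_STREAM_MOTIFS = 5
_STREAM_CONTAM = 6


def simulate_proteome(spec: SimulationSpec) -> list[ProteinRecord]:
    """Random proteins: truncated-normal lengths, background composition."""
    rng = spec.rng(_STREAM_PROTEOME)
    lengths = np.empty(spec.n_proteins, dtype=int)
    filled = 0
    while filled < spec.n_proteins:
        draw = rng.normal(spec.mean_length, spec.sd_length,
                          size=spec.n_proteins - filled)
        ok = np.rint(draw).astype(int)
        ok = ok[ok >= spec.min_length]
        lengths[filled:filled + len(ok)] = ok
        filled += len(ok)
    width = len(str(spec.n_proteins))
    records = []
    for i, L in enumerate(lengths, start=1):
        seq = "".join(rng.choice(_BG_AA, size=L, p=_BG_P))
        records.append(ProteinRecord(f"PROT{i:0{width}d}", seq,
                                     "synthetic background protein"))
    return records


def simulate_intensity_matrix(spec: SimulationSpec,
                              proteome: Sequence[ProteinRecord]):
    """Tissue-panel iBAQ matrix with a planted gland-enriched set.

    Per protein, a baseline log10 intensity is drawn and jittered per
    sample.  A ``tissue_specific_fraction`` of the background proteins are
    tissue specialists, elevated by about ``tissue_effect`` decades in one
    or two randomly chosen non-gland sample groups — the co-expression
    structure (housekeeping plus tissue-restricted programs) that makes a
    tissue panel clusterable at all; the rest are flat housekeepers.
    Planted proteins get +log10(fold) in every femoral-gland
    fraction column and half that effect in seminal fluid.  Cells then drop
    out with probability decreasing in intensity — the detection behaviour
    of MS data, where non-detection concentrates at the low-abundance end —
    calibrated so the expected overall missing fraction is ``missing_rate``.
    Returns the matrix and the frozen set of planted protein ids.
    """
    from .enrichment import IntensityMatrix

    import pandas as pd

    if not proteome:
        raise ValueError("proteome must be non-empty")
    if spec.planted_enriched > len(proteome):
        raise ValueError(
            f"planted_enriched ({spec.planted_enriched}) exceeds proteome "
            f"size ({len(proteome)})"
        )
    rng = spec.rng(_STREAM_INTENSITY)
    roles = default_sample_roles(spec.n_tissues, spec.n_fg_fractions)
    samples = list(roles)
    ids = [p.id for p in proteome]
    n, m = len(ids), len(samples)
    base = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, size=n)
    # shared per-sample offsets (protein load / instrument response) felt by
    # every protein with a protein-specific sensitivity around 1 — the
    # common variation that makes even housekeeping profiles co-vary
    sample_offset = rng.normal(0.0, spec.sample_effect_sd, size=m)
    sensitivity = rng.normal(1.0, 0.25, size=n)
    logv = (base[:, None]
            + sensitivity[:, None] * sample_offset[None, :]
            + rng.normal(0.0, spec.sample_log_sd, size=(n, m)))
    planted_idx = rng.choice(n, size=spec.planted_enriched, replace=False)
    effect = np.log10(spec.enrichment_fold)
    fg_cols = [j for j, s in enumerate(samples) if roles[s] == "FG"]
    sf_col = samples.index("SF")
    # background co-expression structure: non-gland sample groups a
    # specialist protein can be restricted to
    groups = {}
    for j, s in enumerate(samples):
        if roles[s] != "FG":
            groups.setdefault(roles[s] if roles[s] != "tissue" else s,
                              []).append(j)
    group_cols = list(groups.values())
    # every protein enters the specialist lottery, so that at fold=1 the
    # planted subset is exchangeable with the background (a clean null)
    for i in range(n):
        if rng.random() < spec.tissue_specific_fraction:
            n_groups = 1 + int(rng.random() < 0.25)
            for g in rng.choice(len(group_cols), size=n_groups,
                                replace=False):
                boost = spec.tissue_effect * rng.uniform(0.7, 1.3)
                logv[i, group_cols[g]] += boost
    logv[np.ix_(planted_idx, fg_cols)] += effect
    logv[planted_idx, sf_col] += 0.5 * effect
    values = 10.0 ** logv
    if spec.missing_rate > 0:
        # dropout concentrates sharply at the low-abundance end, as at an MS
        # detection limit: p(u) = min(1, c*(1-u)^gamma) on the global
        # intensity rank u, with c set in closed form so the expected
        # missing fraction equals missing_rate
        gamma = 8.0
        mr = spec.missing_rate
        if mr <= 1.0 / (gamma + 1.0):
            c = (gamma + 1.0) * mr
        else:
            t = (1.0 - mr) * (gamma + 1.0) / gamma
            c = t ** -gamma
        order = logv.ravel().argsort().argsort().reshape(logv.shape)
        u = order / (logv.size - 1) if logv.size > 1 else np.zeros_like(logv)
        p_miss = np.minimum(1.0, c * (1.0 - u) ** gamma)
        mask = rng.random(size=(n, m)) < p_miss
        values = np.where(mask, np.nan, values)
    matrix = IntensityMatrix(
        data=pd.DataFrame(values, index=ids, columns=samples),
        roles=roles,
    )
    truth = frozenset(ids[i] for i in planted_idx)
    return matrix, truth


def _amp_like_sequence(rng: np.random.Generator, length: int,
                       charge_bias: float, hydropathy_bias: float) -> str:
    """One cationic, period-2 amphipathic peptide.

    Each position independently becomes K/R with probability ``charge_bias``;
    otherwise, with probability ``hydropathy_bias`` it is drawn from a
    hydrophobic set at even offsets and a polar set at odd offsets
    (period-2 hydropathy alternation), else from the background table.
    """
    out = []
    for i in range(length):
        u = rng.random()
        if u < charge_bias:
            out.append("K" if rng.random() < 0.5 else "R")
        elif rng.random() < hydropathy_bias:
            pool = _HYDROPHOBIC if i % 2 == 0 else _POLAR
            out.append(str(rng.choice(pool)))
        else:
            out.append(str(rng.choice(_BG_AA, p=_BG_P)))
    return "".join(out)


def simulate_amp_corpus(spec: SimulationSpec
                        ) -> list[tuple[str, str, int]]:
    """Labelled training peptides: AMP-like positives, background negatives.

    Both classes draw lengths uniformly on [5, 100].  Positives carry the
    charge and amphipathy biases; negatives are plain background
    composition.  Returns (id, sequence, label) triples, label 1 = AMP.
    """
    rng = spec.rng(_STREAM_CORPUS)
    out: list[tuple[str, str, int]] = []
    for i in range(spec.n_amp):
        L = int(rng.integers(5, 101))
        out.append((f"AMP{i + 1:04d}",
                    _amp_like_sequence(rng, L, spec.amp_charge_bias,
                                       spec.amp_hydropathy_bias), 1))
    for i in range(spec.n_background):
        L = int(rng.integers(5, 101))
        seq = "".join(rng.choice(_BG_AA, size=L, p=_BG_P))
        out.append((f"BG{i + 1:04d}", seq, 0))
    return out


def simulate_hit_table(
    proteome: Sequence[ProteinRecord],
    spec: SimulationSpec,
    fraction: float | None = None,
    log10_evalue_annotated: tuple[float, float] = (-250.0, -21.0),
    log10_evalue_weak: tuple[float, float] = (-19.5, 0.5),
):
    """Cross-species hit table with planted orthology.

    ``fraction`` (default ``spec.hit_fraction``) of the proteome receives a
    qualifying best hit: one organism drawn with a log10 E-value inside
    ``log10_evalue_annotated`` (below the transfer cutoff), plus hits in a
    random subset of further organisms spread over ``log10_evalue_weak``
    (spanning the weak and no-homology classes).  The remaining proteins get
    either no hits or only weak ones.  Returns the hit list and a dict
    protein id -> planted ortholog subject id (``None`` for unannotated).
    """
    rng = spec.rng(_STREAM_HITS)
    frac = spec.hit_fraction if fraction is None else fraction
    n = len(proteome)
    n_annot = int(round(frac * n))
    annotated_idx = set(rng.choice(n, size=n_annot, replace=False).tolist())
    hits: list[HitRecord] = []
    truth: dict[str, str | None] = {}

    def make_hit(query: str, organism: str, log10e: float) -> HitRecord:
        evalue = float(10.0 ** log10e)
        bitscore = float(max(20.0, -2.0 * log10e + rng.normal(0.0, 5.0)))
        identity = float(np.clip(55.0 - 0.15 * log10e + rng.normal(0, 8),
                                 20.0, 100.0))
        subject = f"{organism}|{query}_homolog"
        return HitRecord(query_id=query, subject_id=subject,
                         organism=organism, evalue=evalue,
                         identity=identity, bitscore=bitscore,
                         align_len=int(rng.integers(50, 400)))

    for i, rec in enumerate(proteome):
        organisms = rng.permutation(len(ORGANISMS))
        if i in annotated_idx:
            n_orgs = int(rng.integers(1, len(ORGANISMS) + 1))
            chosen = [ORGANISMS[j] for j in organisms[:n_orgs]]
            best_log10e = float(rng.uniform(*log10_evalue_annotated))
            best = make_hit(rec.id, chosen[0], best_log10e)
            hits.append(best)
            truth[rec.id] = best.subject_id
            for org in chosen[1:]:
                log10e = float(rng.uniform(best_log10e, 1.0))
                hits.append(make_hit(rec.id, org, log10e))
        else:
            truth[rec.id] = None
            if rng.random() < 0.5:
                continue  # a true orphan: no hits at all
            n_orgs = int(rng.integers(1, 4))
            for org in (ORGANISMS[j] for j in organisms[:n_orgs]):
                log10e = float(rng.uniform(*log10_evalue_weak))
                hits.append(make_hit(rec.id, org, log10e))
    return hits, truth


def simulate_contaminant_table(
    proteome: Sequence[ProteinRecord],
    spec: SimulationSpec,
    fraction: float = 0.01,
    log10_evalue: tuple[float, float] = (-120.0, -40.0),
):
    """Bacterial-database hits for a small planted contaminant fraction."""
    rng = spec.rng(_STREAM_CONTAM)
    n = len(proteome)
    n_contam = int(round(fraction * n))
    idx = rng.choice(n, size=n_contam, replace=False)
    hits = []
    truth = frozenset(proteome[i].id for i in idx)
    for i in idx:
        log10e = float(rng.uniform(*log10_evalue))
        hits.append(HitRecord(
            query_id=proteome[i].id,
            subject_id=f"Ecoli|{proteome[i].id}_contam",
            organism="Escherichia_coli",
            evalue=float(10.0 ** log10e),
            identity=float(rng.uniform(80.0, 100.0)),
            bitscore=float(-2.0 * log10e),
            align_len=int(rng.integers(50, 400)),
        ))
    return hits, truth


def plant_amp_motifs(
    proteome: Sequence[ProteinRecord],
    spec: SimulationSpec,
    n_motifs: int = 20,
    motif_length: tuple[int, int] = (10, 15),
):
    """Overwrite AMP-like segments into randomly chosen proteins.

    Returns the modified proteome plus the planted loci as (protein_id,
    start, end) half-open intervals — the ground truth for window-recovery
    experiments.
    """
    rng = spec.rng(_STREAM_MOTIFS)
    eligible = [i for i, p in enumerate(proteome)
                if len(p) >= motif_length[1]]
    if len(eligible) < n_motifs:
        raise ValueError("not enough long proteins to plant motifs into")
    chosen = rng.choice(len(eligible), size=n_motifs, replace=False)
    out = list(proteome)
    loci: list[tuple[str, int, int]] = []
    for ci in chosen:
        i = eligible[ci]
        rec = out[i]
        L = int(rng.integers(motif_length[0], motif_length[1] + 1))
        start = int(rng.integers(0, len(rec) - L + 1))
        motif = _amp_like_sequence(rng, L, spec.amp_charge_bias,
                                   spec.amp_hydropathy_bias)
        seq = rec.sequence[:start] + motif + rec.sequence[start + L:]
        out[i] = ProteinRecord(rec.id, seq, rec.description)
        loci.append((rec.id, start, start + L))
    return out, loci


def hill_inhibition(c: np.ndarray | float, ec50: float, h: float,
                    emax: float = 1.0) -> np.ndarray | float:
    """Fractional growth inhibition of the Hill dose-response model."""
    c = np.asarray(c, dtype=float)
    return emax * c ** h / (ec50 ** h + c ** h)


def simulate_plate(
    spec: SimulationSpec,
    concentrations: Sequence[float],
    emax: float = 1.0,
    replicates: int = 2,
    peptide_id: str = "peptide",
    strain: str = "E_coli_K12",
    rng: np.random.Generator | None = None,
):
    """Duplicate OD600 readings from a Hill dose-response.

    Control wells read 1.0 before noise; a test well at concentration ``c``
    reads ``1 - emax * c^h / (EC50^h + c^h)`` before noise.  Gaussian noise
    of SD ``od_noise_sd`` is added independently to every well.
    """
    from .assay import PlateAssay

    if rng is None:
        rng = spec.rng(_STREAM_PLATE)
    concs = tuple(sorted((float(c) for c in concentrations), reverse=True))
    od_test = []
    for c in concs:
        clean = 1.0 - float(hill_inhibition(c, spec.dose_ec50,
                                            spec.dose_hill, emax))
        od_test.append(tuple(
            clean + float(rng.normal(0.0, spec.od_noise_sd))
            for _ in range(replicates)
        ))
    od_control = tuple(
        1.0 + float(rng.normal(0.0, spec.od_noise_sd))
        for _ in range(replicates)
    )
    return PlateAssay(
        peptide_id=peptide_id,
        strain=strain,
        concentrations=concs,
        od_test=tuple(od_test),
        od_control=od_control,
        od_blank=None,
    )
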