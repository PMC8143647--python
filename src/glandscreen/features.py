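"""Peptide descriptors: pseudo amino acid composition and physicochemistry.

The classifier features combine Chou's pseudo amino acid composition
(PseAAC) with a handful of global physicochemical descriptors.  PseAAC
extends the 20 amino-acid frequencies with ``lambda`` sequence-order
correlation factors

    theta_j = (1 / (L - j)) * sum_i  Theta(r_i, r_{i+j}),   j = 1..lambda,

where ``Theta(a, b)`` averages the squared differences of three normalised
residue properties — hydrophobicity, hydrophilicity and side-chain mass, the
trio of the original formulation.  Each property is standardised over the 20
residues (zero mean, unit population SD) before use.  The full vector

    x_u = f_u / (sum f + w * sum theta)           for u = 1..20
    x_{20+j} = w * theta_j / (sum f + w * sum theta)

sums to exactly 1, with ``w`` weighting the sequence-order part (classic
default 0.05).

Auxiliary descriptors: net charge at pH 7 from a per-residue
Henderson-Hasselbalch model, isoelectric point by bisection of the same
model, GRAVY (Kyte-Doolittle mean hydropathy), the Guruprasad instability
index (dipeptide weights from Biopython's table), aromaticity, and length.

A vectorised batch path (`feature_matrix`) makes scanning millions of
sliding windows tractable; the scalar `compute_features` path is the
readable reference and the two agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.SeqUtils import ProtParamData

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

# Residue property tables used by the sequence-correlation factors.
# Hydrophobicity: Tanford-derived scale of the original PseAAC formulation;
# hydrophilicity: Hopp-Woods; side-chain mass in Da.
_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}
_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
    "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
    "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
    "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}
_SIDECHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0,
    "G": 1.0, "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0,
    "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0, "R": 101.0,
    "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0,
}

# Henderson-Hasselbalch pKa model (EMBOSS values); termini always included.
PKA_POSITIVE = {"K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}
PKA_NTERM = 8.6
PKA_CTERM = 3.6

_KYTE_DOOLITTLE = ProtParamData.kd
#: residues counted as hydrophobic by the solubility proxy
HYDROPHOBIC_RESIDUES = frozenset("ACFILMVW")


def _standardised(table: dict[str, float]) -> np.ndarray:
    v = np.array([table[a] for a in AMINO_ACIDS])
    return (v - v.mean()) / v.std()  # population SD over the 20 residues


_PROPS = np.stack([
    _standardised(_HYDROPHOBICITY),
    _standardised(_HYDROPHILICITY),
    _standardised(_SIDECHAIN_MASS),
])
#: Theta(a, b): mean squared difference of the three normalised properties
THETA_TABLE = ((_PROPS[:, :, None] - _PROPS[:, None, :]) ** 2).mean(axis=0)

_KD_VEC = np.array([_KYTE_DOOLITTLE[a] for a in AMINO_ACIDS])
_AROMATIC_VEC = np.array([1.0 if a in "FWY" else 0.0 for a in AMINO_ACIDS])
_HPHOB_VEC = np.array([1.0 if a in HYDROPHOBIC_RESIDUES else 0.0
                       for a in AMINO_ACIDS])
_DIWV = np.zeros((20, 20))
for _a, _row in ProtParamData.DIWV.items():
    for _b, _w in _row.items():
        if _a in _AA_INDEX and _b in _AA_INDEX:
            _DIWV[_AA_INDEX[_a], _AA_INDEX[_b]] = _w

#: names of the auxiliary (non-PseAAC) feature columns, in order
AUX_FEATURES = ("net_charge", "gravy", "instability", "aromaticity",
                "iso_point", "length")


def encode(sequence: str) -> np.ndarray:
    """Map a peptide to integer residue codes; rejects non-standard letters."""
    try:
        return np.array([_AA_INDEX[a] for a in sequence], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(
            f"non-standard residue {exc.args[0]!r} in sequence {sequence!r}"
        ) from None


@dataclass(frozen=True)
class FeatureVector:
    """Descriptors of one peptide; `to_array` yields the classifier input."""

    aac: np.ndarray            # 20 amino-acid frequencies (pre-normalisation)
    pseaac: np.ndarray         # full 20+lambda PseAAC vector, sums to 1
    pseaac_theta: np.ndarray   # the lambda raw correlation factors
    net_charge: float
    gravy: float
    instability: float
    aromaticity: float
    iso_point: float
    length: int
    lam: int
    weight: float

    def to_array(self) -> np.ndarray:
        return np.concatenate([
            self.pseaac,
            [self.net_charge, self.gravy, self.instability,
             self.aromaticity, self.iso_point, float(self.length)],
        ])


def _charge_at_ph(counts: np.ndarray, ph: float | np.ndarray) -> np.ndarray:
    """Net charge for residue-count vectors (.., 20) at the given pH."""
    ph = np.asarray(ph, dtype=float)
    pos = np.zeros(np.broadcast_shapes(counts.shape[:-1], ph.shape))
    for aa, pka in PKA_POSITIVE.items():
        pos = pos + counts[..., _AA_INDEX[aa]] / (1.0 + 10.0 ** (ph - pka))
    pos = pos + 1.0 / (1.0 + 10.0 ** (ph - PKA_NTERM))
    neg = np.zeros_like(pos)
    for aa, pka in PKA_NEGATIVE.items():
        neg = neg + counts[..., _AA_INDEX[aa]] / (1.0 + 10.0 ** (pka - ph))
    neg = neg + 1.0 / (1.0 + 10.0 ** (PKA_CTERM - ph))
    return pos - neg


def net_charge(sequence: str, ph: float = 7.0) -> float:
    """Net charge of a free peptide (charged termini) at the given pH."""
    counts = np.bincount(encode(sequence), minlength=20).astype(float)
    return float(_charge_at_ph(counts, ph))


def isoelectric_point(sequence: str) -> float:
    counts = np.bincount(encode(sequence), minlength=20).astype(float)
    return float(_isoelectric_from_counts(counts[None, :])[0])


def _isoelectric_from_counts(counts: np.ndarray, iters: int = 60) -> np.ndarray:
    """Vectorised bisection of charge(pH) = 0 on [0, 14] per row."""
    lo = np.zeros(counts.shape[0])
    hi = np.full(counts.shape[0], 14.0)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        q = _charge_at_ph(counts, mid)
        lo = np.where(q > 0, mid, lo)
        hi = np.where(q > 0, hi, mid)
    return 0.5 * (lo + hi)


def pseaac(sequence: str, lam: int = 4, weight: float = 0.05) -> np.ndarray:
    """Chou's pseudo amino acid composition: a (20 + lam)-vector summing to 1."""
    codes = encode(sequence)
    return _pseaac_batch(codes[None, :], lam, weight)[0]


def _theta_batch(codes: np.ndarray, lam: int) -> np.ndarray:
    """Correlation factors theta_1..theta_lam for an (N, L) code array."""
    n, L = codes.shape
    if lam >= L:
        raise ValueError(f"sequence length {L} must exceed lambda={lam}")
    thetas = np.empty((n, lam))
    for j in range(1, lam + 1):
        thetas[:, j - 1] = THETA_TABLE[codes[:, :-j], codes[:, j:]].mean(axis=1)
    return thetas if lam else np.empty((n, 0))


def _pseaac_batch(codes: np.ndarray, lam: int, weight: float) -> np.ndarray:
    n, L = codes.shape
    freqs = np.zeros((n, 20))
    for a in range(20):
        freqs[:, a] = (codes == a).sum(axis=1)
    freqs /= L
    thetas = _theta_batch(codes, lam) if lam > 0 else np.empty((n, 0))
    denom = 1.0 + weight * thetas.sum(axis=1, keepdims=True)
    return np.hstack([freqs / denom, weight * thetas / denom])


def compute_features(sequence: str, lam: int = 4, weight: float = 0.05
                     ) -> FeatureVector:
    """All descriptors of one peptide; requires length > lambda."""
    if len(sequence) <= lam:
        raise ValueError(
            f"sequence of length {len(sequence)} is too short for "
            f"lambda={lam} (need length > lambda)"
        )
    codes = encode(sequence)
    counts = np.bincount(codes, minlength=20).astype(float)
    aac = counts / len(sequence)
    vec = _pseaac_batch(codes[None, :], lam, weight)[0]
    thetas = _theta_batch(codes[None, :], lam)[0] if lam else np.empty(0)
    L = len(sequence)
    instab = 0.0 if L < 2 else 10.0 / L * _DIWV[codes[:-1], codes[1:]].sum()
    return FeatureVector(
        aac=aac,
        pseaac=vec,
        pseaac_theta=thetas,
        net_charge=float(_charge_at_ph(counts, 7.0)),
        gravy=float(_KD_VEC[codes].mean()),
        instability=float(instab),
        aromaticity=float(_AROMATIC_VEC[codes].mean()),
        iso_point=float(_isoelectric_from_counts(counts[None, :])[0]),
        length=L,
        lam=lam,
        weight=weight,
    )


def feature_names(lam: int = 4) -> list[str]:
    names = [f"aac_{a}" for a in AMINO_ACIDS]
    names += [f"theta_{j}" for j in range(1, lam + 1)]
    names += list(AUX_FEATURES)
    return names


def feature_matrix(sequences: Sequence[str], lam: int = 4,
                   weight: float = 0.05) -> np.ndarray:
    """Feature matrix for many peptides, batched by length for speed.

    Row order matches the input order; every sequence must be longer than
    ``lam`` and standard-alphabet.  Output has 20 + lam + 6 columns
    (:func:`feature_names`).
    """
    n = len(sequences)
    out = np.empty((n, 26 + lam))
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(sequences):
        if len(s) <= lam:
            raise ValueError(
                f"sequence of length {len(s)} too short for lambda={lam}"
            )
        by_len.setdefault(len(s), []).append(i)
    for L, idx in by_len.items():
        codes = np.stack([encode(sequences[i]) for i in idx])
        vec = _pseaac_batch(codes, lam, weight)
        counts = np.zeros((len(idx), 20))
        for a in range(20):
            counts[:, a] = (codes == a).sum(axis=1)
        charge = _charge_at_ph(counts, 7.0)
        gravy = _KD_VEC[codes].mean(axis=1)
        if L >= 2:
            instab = 10.0 / L * _DIWV[codes[:, :-1], codes[:, 1:]].sum(axis=1)
        else:
            instab = np.zeros(len(idx))
        arom = _AROMATIC_VEC[codes].mean(axis=1)
        pi = _isoelectric_from_counts(counts)
        block = np.hstack([
            vec,
            np.column_stack([charge, gravy, instab, arom, pi,
                             np.full(len(idx), float(L))]),
        ])
        out[idx, :] = block
    return out


def hydrophobic_fraction(sequence: str) -> float:
    codes = encode(sequence)
    return float(_HPHOB_VEC[codes].mean())
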