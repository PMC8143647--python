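"""Broth-microdilution analysis: inhibition curves, MIC, dose dependence.

A test substance is serially two-fold diluted from a stock (1 mg/ml down to
~31 ug/ml in the reference protocol), incubated with the culture in
duplicate wells, and growth is read as OD600.  Relative growth inhibition
at each concentration compares the mean test reading with a no-substance
control, optionally blank-corrected:

    inhibition% = 100 * (1 - (mean(OD_test) - blank) / (mean(OD_ctrl) - blank))

The MIC is operationalised as the lowest tested concentration whose
inhibition reaches a threshold (default 90%).  Dose dependence is the
one-sided exact-permutation test of a positive Spearman correlation between
concentration and inhibition.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy.stats import spearmanr

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlateAssay:
    """Dilution-series OD600 readings for one peptide on one strain."""

    peptide_id: str
    strain: str
    concentrations: tuple[float, ...]       # ug/ml, strictly decreasing
    od_test: tuple[tuple[float, ...], ...]  # replicates per concentration
    od_control: tuple[float, ...]           # no-substance wells
    od_blank: tuple[float, ...] | None = None  # medium-only wells

    def __post_init__(self) -> None:
        if len(self.od_test) != len(self.concentrations):
            raise ValueError("one replicate tuple required per concentration")
        if any(len(reps) < 1 for reps in self.od_test):
            raise ValueError("every concentration needs at least one replicate")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be positive")
        if any(a <= b for a, b in zip(self.concentrations,
                                      self.concentrations[1:])):
            raise ValueError("concentrations must be strictly decreasing")
        if len(self.od_control) < 1:
            raise ValueError("at least one control well is required")


@dataclass(frozen=True)
class InhibitionCurve:
    peptide_id: str
    strain: str
    concentrations: tuple[float, ...]
    inhibition_percent: tuple[float, ...]
    max_inhibition: float
    mic: float | None
    mic_threshold: float
    dose_dependent: bool
    spearman_rho: float
    spearman_p: float


def dilution_series(stock: float, factor: float = 2.0,
                    floor: float = 31.0) -> list[Fraction]:
    """Serial dilution from ``stock``, stopping below ``floor``.

    Values are exact rationals (``Fraction``), halved (or divided by
    ``factor``) repeatedly while still >= floor; a stock already below the
    floor yields an empty series with a warning.  The reference series is
    1000 -> 500 -> 250 -> 125 -> 62.5 -> 31.25 ug/ml.
    """
    if factor <= 1:
        raise ValueError("dilution factor must exceed 1")
    if stock <= 0:
        raise ValueError("stock concentration must be positive")
    series: list[Fraction] = []
    c = Fraction(stock).limit_denominator(10**9)
    f = Fraction(factor).limit_denominator(10**9)
    fl = Fraction(floor).limit_denominator(10**9)
    while c >= fl:
        series.append(c)
        c = c / f
    if not series:
        log.warning("stock %s ug/ml is below the floor %s ug/ml: empty series",
                    stock, floor)
    return series


def relative_inhibition(
    od_test: Sequence[float] | float,
    od_control: Sequence[float] | float,
    od_blank: Sequence[float] | float | None = None,
) -> float:
    """Percent growth inhibition of test wells relative to the control.

    Replicates are averaged before the ratio.  The blank defaults to 0 when
    absent; a control at or below the blank (no growth) is a hard error.
    Results are clamped to [0, 100] with a log line when clamping occurs.
    """
    test = float(np.mean(od_test))
    control = float(np.mean(od_control))
    blank = 0.0 if od_blank is None else float(np.mean(od_blank))
    if control <= blank:
        raise ValueError(
            f"control OD {control} does not exceed blank {blank}: "
            "no growth in the control wells"
        )
    raw = 100.0 * (1.0 - (test - blank) / (control - blank))
    if raw < 0.0:
        log.info("inhibition %.2f%% clamped to 0%%", raw)
        return 0.0
    if raw > 100.0:
        log.info("inhibition %.2f%% clamped to 100%%", raw)
        return 100.0
    return raw


def mic_call(concentrations: Sequence[float],
             inhibition_percent: Sequence[float],
             threshold: float = 90.0) -> float | None:
    """Lowest tested concentration whose inhibition reaches the threshold."""
    qualifying = [c for c, i in zip(concentrations, inhibition_percent)
                  if i >= threshold]
    return min(qualifying) if qualifying else None


def _exact_spearman_p(conc: np.ndarray, inhib: np.ndarray) -> tuple[float, float]:
    """One-sided (rho > 0) exact permutation p for the Spearman correlation.

    Enumerates all permutations of the inhibition values — feasible for the
    <= 8 concentrations of a microdilution series.
    """
    rho = spearmanr(conc, inhib).statistic
    if not np.isfinite(rho):
        return float("nan"), 1.0
    n = len(conc)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = spearmanr(conc, inhib[list(perm)]).statistic
        if np.isfinite(r) and r >= rho - 1e-12:
            count += 1
        total += 1
    return float(rho), count / total


def dose_dependence(concentrations: Sequence[float],
                    inhibition_percent: Sequence[float],
                    alpha: float = 0.05) -> tuple[bool, float, float]:
    """(dose_dependent, rho, p): positive Spearman trend at exact-perm p < alpha.

    A constant inhibition profile has an undefined correlation; it is
    reported as rho = 0 with p = 1 and judged not dose dependent.
    """
    conc = np.asarray(concentrations, dtype=float)
    inhib = np.asarray(inhibition_percent, dtype=float)
    if len(conc) != len(inhib):
        raise ValueError("concentration/inhibition length mismatch")
    if len(conc) < 3:
        return False, 0.0, 1.0
    if np.allclose(inhib, inhib[0]):
        return False, 0.0, 1.0
    if len(conc) > 8:
        # exact enumeration is for short series; fall back to the asymptotic p
        res = spearmanr(conc, inhib, alternative="greater")
        rho, p = float(res.statistic), float(res.pvalue)
    else:
        rho, p = _exact_spearman_p(conc, inhib)
    if not np.isfinite(rho):
        return False, 0.0, 1.0
    return bool(rho > 0 and p < alpha), rho, p


def analyze_plate(assay: PlateAssay, mic_threshold: float = 90.0,
                  alpha: float = 0.05) -> InhibitionCurve:
    """Full per-plate analysis: inhibition curve, MIC and dose dependence."""
    inhibition = tuple(
        relative_inhibition(reps, assay.od_control, assay.od_blank)
        for reps in assay.od_test
    )
    mic = mic_call(assay.concentrations, inhibition, mic_threshold)
    dd, rho, p = dose_dependence(assay.concentrations, inhibition)
    return InhibitionCurve(
        peptide_id=assay.peptide_id,
        strain=assay.strain,
        concentrations=assay.concentrations,
        inhibition_percent=inhibition,
        max_inhibition=max(inhibition) if inhibition else 0.0,
        mic=mic,
        mic_threshold=mic_threshold,
        dose_dependent=dd,
        spearman_rho=rho,
        spearman_p=p,
    )


def per_replicate_curves(assay: PlateAssay) -> list[tuple[float, ...]]:
    """Inhibition per individual replicate (no averaging), one tuple per well.

    Emitted alongside the mean curve so duplicate scatter stays visible.
    """
    n_reps = max(len(r) for r in assay.od_test)
    curves = []
    for rep in range(n_reps):
        vals = []
        for reps in assay.od_test:
            od = reps[rep] if rep < len(reps) else reps[-1]
            vals.append(relative_inhibition([od], assay.od_control,
                                            assay.od_blank))
        curves.append(tuple(vals))
    return curves


def write_curves_tsv(curves: Sequence[InhibitionCurve], path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide_id\tstrain\tconcentration_ug_ml\tinhibition_percent"
                 "\tmax_inhibition\tmic\tmic_threshold\tdose_dependent"
                 "\tspearman_rho\tspearman_p\n")
        for c in curves:
            for conc, inh in zip(c.concentrations, c.inhibition_percent):
                fh.write(
                    f"{c.peptide_id}\t{c.strain}\t{conc:g}\t{inh:.6g}\t"
                    f"{c.max_inhibition:.6g}\t"
                    f"{'' if c.mic is None else format(c.mic, 'g')}\t"
                    f"{c.mic_threshold:g}\t{int(c.dose_dependent)}\t"
                    f"{c.spearman_rho:.6g}\t{c.spearman_p:.6g}\n"
                )
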