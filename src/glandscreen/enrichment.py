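"""Femoral-gland enrichment calling from an iBAQ intensity matrix.

The gland secretion of a holocrine organ contains whole glandular cells, so
housekeeping proteins shared with every tissue dominate the raw protein
list.  Two complementary selections isolate the gland-specific signal:

* **unique set** — proteins detected in the femoral-gland (FG) secretion and
  in no other sample (computed on the unfiltered matrix, since such proteins
  by construction fail the valid-value filter);
* **enriched set** — proteins that pass a valid-value filter (>=1 FG value
  and >=2 values elsewhere), are z-scored per protein on log10 intensity,
  clustered by k-means, and retained when they belong to the cluster whose
  centroid is highest in FG *and* their score on the first principal
  component of the FG/seminal-fluid (SF) submatrix exceeds a quantile
  threshold.  The component is oriented so that FG-high proteins score
  positive.

The union of the two sets, ranked by FG intensity, is the gland-specific
proteome.  Serum columns are dropped before filtering (few proteins are
detected there and the sample is uninformative for enrichment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

#: recognised sample role tags
ROLES = ("FG", "SF", "serum", "tissue", "erythrocyte")


class ZeroVarianceError(ValueError):
    """Raised when a protein's detected intensities are all identical."""

    def __init__(self, protein_ids: Sequence[str]):
        self.protein_ids = list(protein_ids)
        super().__init__(
            "zero-variance intensity rows (cannot z-score): "
            + ", ".join(map(str, self.protein_ids))
        )


@dataclass
class IntensityMatrix:
    """Protein x sample intensities with missingness, plus sample role tags.

    ``data`` holds raw (linear-scale) intensities with NaN for "not
    detected".  ``roles`` maps each sample name to one of :data:`ROLES`; when
    omitted, roles are inferred from sample-name prefixes (``FG*`` -> FG,
    ``SF*`` -> SF, ``serum*`` -> serum, ``ery*`` -> erythrocyte, everything
    else -> tissue).
    """

    data: pd.DataFrame
    roles: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate protein ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample names")
        if self.roles is None:
            self.roles = {c: _infer_role(c) for c in self.data.columns}
        else:
            missing = set(self.data.columns) - set(self.roles)
            if missing:
                raise ValueError(f"samples without a role tag: {sorted(missing)}")
        if not self.samples_with_role("FG"):
            raise ValueError("matrix must contain at least one FG-tagged sample")

    def samples_with_role(self, role: str) -> list[str]:
        return [c for c in self.data.columns if self.roles[c] == role]

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    def drop_role(self, role: str) -> "IntensityMatrix":
        keep = [c for c in self.data.columns if self.roles[c] != role]
        return IntensityMatrix(
            data=self.data[keep].copy(),
            roles={c: self.roles[c] for c in keep},
        )

    def fg_intensity(self) -> pd.Series:
        """Mean detected FG intensity per protein (NaN when undetected)."""
        fg = self.data[self.samples_with_role("FG")]
        return fg.mean(axis=1, skipna=True)


def _infer_role(sample: str) -> str:
    low = sample.lower()
    if low.startswith("fg"):
        return "FG"
    if low.startswith("sf"):
        return "SF"
    if low.startswith("serum"):
        return "serum"
    if low.startswith("ery"):
        return "erythrocyte"
    return "tissue"


@dataclass(frozen=True)
class EnrichmentResult:
    unique_set: frozenset[str]
    enriched_set: frozenset[str]
    combined_set: frozenset[str]
    cluster_labels: Mapping[str, int]
    fg_cluster: int
    pca_loadings: Mapping[str, float]
    ranking: tuple[str, ...]


def filter_valid(matrix: IntensityMatrix) -> IntensityMatrix:
    """Apply the valid-value filter used before clustering.

    Serum samples are dropped first; a protein is retained when it has at
    least one detected FG value and at least two detected values among the
    remaining non-FG samples.  The filter is idempotent.
    """
    m = matrix.drop_role("serum")
    fg_cols = m.samples_with_role("FG")
    other_cols = [c for c in m.data.columns if c not in fg_cols]
    fg_ok = m.data[fg_cols].notna().sum(axis=1) >= 1
    other_ok = m.data[other_cols].notna().sum(axis=1) >= 2
    keep = fg_ok & other_ok
    return IntensityMatrix(
        data=m.data.loc[keep].copy(),
        roles=dict(m.roles),
    )


def zscore_transform(
    matrix: IntensityMatrix,
    downshift: float = 0.5,
) -> IntensityMatrix:
    """Per-protein z-score of log10 intensities, missing values downshifted.

    Each row's detected intensities are log10-transformed, centred and scaled
    by their standard deviation (population, ddof=0).  Missing cells are then
    imputed at the row-minimum z minus ``downshift`` so clustering sees
    complete vectors while non-detection stays at the low-abundance end.
    Rows with zero variance across detected values are a hard error.
    """
    values = matrix.data.to_numpy(dtype=float)
    logv = np.where(np.isfinite(values), np.log10(values), np.nan)
    mean = np.nanmean(logv, axis=1, keepdims=True)
    sd = np.nanstd(logv, axis=1, keepdims=True, ddof=0)
    flat = np.where(sd[:, 0] == 0)[0]
    if flat.size:
        raise ZeroVarianceError([matrix.data.index[i] for i in flat])
    z = (logv - mean) / sd
    rowmin = np.nanmin(z, axis=1, keepdims=True)
    z = np.where(np.isnan(z), rowmin - downshift, z)
    return IntensityMatrix(
        data=pd.DataFrame(z, index=matrix.data.index, columns=matrix.data.columns),
        roles=dict(matrix.roles),
    )


def cluster_proteins(
    zmatrix: IntensityMatrix,
    k: int = 6,
    seed: int = 0,
) -> tuple[dict[str, int], int]:
    """k-means over protein z-profiles; returns labels and the FG cluster.

    Uses k-means++ initialisation with a fixed seed and at most 300
    iterations.  The FG-enriched cluster is the one whose centroid has the
    highest mean coordinate over the FG columns.
    """
    X = zmatrix.data.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("z-matrix contains non-finite values; impute first")
    k = min(k, X.shape[0])
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300,
                random_state=seed)
    labels = km.fit_predict(X)
    fg_idx = [zmatrix.data.columns.get_loc(c)
              for c in zmatrix.samples_with_role("FG")]
    fg_coord = km.cluster_centers_[:, fg_idx].mean(axis=1)
    fg_cluster = int(np.argmax(fg_coord))
    return (
        {pid: int(l) for pid, l in zip(zmatrix.data.index, labels)},
        fg_cluster,
    )


def pca_fg_loadings(zmatrix: IntensityMatrix) -> dict[str, float]:
    """Protein scores on PC1 of the FG/SF submatrix, FG-high oriented.

    The principal axes are computed on the z-matrix restricted to FG- and
    SF-tagged columns.  The first component's sign is normalised so that its
    FG coordinate (mean over FG columns) is positive, making "high loading"
    mean "high in the gland" regardless of SVD sign convention.
    """
    cols = zmatrix.samples_with_role("FG") + zmatrix.samples_with_role("SF")
    if not cols:
        raise ValueError("no FG/SF columns for the loading analysis")
    X = zmatrix.data[cols].to_numpy(dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    # PC1 via SVD; deterministic up to sign, which we fix below
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    pc1 = vt[0]
    n_fg = len(zmatrix.samples_with_role("FG"))
    if pc1[:n_fg].mean() < 0:
        pc1 = -pc1
    scores = Xc @ pc1
    return {pid: float(s) for pid, s in zip(zmatrix.data.index, scores)}


def select_enriched(
    zmatrix: IntensityMatrix,
    labels: Mapping[str, int],
    fg_cluster: int,
    loading_quantile: float = 0.75,
) -> tuple[frozenset[str], dict[str, float]]:
    """Members of the FG cluster whose PC1 score exceeds a quantile threshold.

    ``loading_quantile`` is taken over the PC1 scores of *all* proteins.  The
    comparison is strict, so 0 degenerates to the whole FG cluster and 1 to
    at most one protein (nothing exceeds the maximum unless it is unique).
    """
    loadings = pca_fg_loadings(zmatrix)
    vals = np.array(list(loadings.values()))
    if loading_quantile <= 0:
        selected = {p for p, l in labels.items() if l == fg_cluster}
        return frozenset(selected), loadings
    thr = float(np.quantile(vals, loading_quantile))
    selected = {
        p for p, l in labels.items()
        if l == fg_cluster and loadings[p] > thr
    }
    return frozenset(selected), loadings


def unique_to_fg(matrix: IntensityMatrix) -> frozenset[str]:
    """Proteins detected only in FG samples, on the unfiltered matrix."""
    fg_cols = matrix.samples_with_role("FG")
    other_cols = [c for c in matrix.data.columns if c not in fg_cols]
    fg_any = matrix.data[fg_cols].notna().any(axis=1)
    other_none = ~matrix.data[other_cols].notna().any(axis=1)
    return frozenset(matrix.data.index[fg_any & other_none])


def combine_and_rank(
    unique_set: frozenset[str],
    enriched_set: frozenset[str],
    matrix: IntensityMatrix,
    cluster_labels: Mapping[str, int] | None = None,
    fg_cluster: int = -1,
    pca_loadings: Mapping[str, float] | None = None,
) -> EnrichmentResult:
    """Union the two selections and rank by FG intensity (descending).

    Ties in intensity (including proteins never detected in FG, which rank
    last) are broken by protein id for determinism.
    """
    combined = frozenset(unique_set) | frozenset(enriched_set)
    fg = matrix.fg_intensity()
    def key(pid: str):
        v = fg.get(pid, np.nan)
        return (-(v if np.isfinite(v) else -np.inf), pid)
    ranking = tuple(sorted(combined, key=key))
    return EnrichmentResult(
        unique_set=frozenset(unique_set),
        enriched_set=frozenset(enriched_set),
        combined_set=combined,
        cluster_labels=dict(cluster_labels or {}),
        fg_cluster=fg_cluster,
        pca_loadings=dict(pca_loadings or {}),
        ranking=ranking,
    )


def call_enrichment(
    matrix: IntensityMatrix,
    k: int = 6,
    loading_quantile: float = 0.75,
    downshift: float = 0.5,
    seed: int = 0,
) -> EnrichmentResult:
    """Full enrichment pipeline: filter, z-score, cluster, select, combine."""
    unique = unique_to_fg(matrix)
    filtered = filter_valid(matrix)
    z = zscore_transform(filtered, downshift=downshift)
    labels, fg_cluster = cluster_proteins(z, k=k, seed=seed)
    enriched, loadings = select_enriched(z, labels, fg_cluster, loading_quantile)
    return combine_and_rank(unique, enriched, matrix, labels, fg_cluster, loadings)


def fraction_abundance(
    matrix: IntensityMatrix,
    top_n: int = 5,
) -> pd.DataFrame:
    """Per-sample intensity shares of the most abundant proteins.

    Treats each column as one gel fraction; a protein's share is its
    intensity divided by the fraction's detected total, in percent.  Returns
    a long-form frame (sample, rank, protein_id, intensity, share_percent)
    with the top ``top_n`` proteins per fraction.
    """
    rows = []
    for col in matrix.data.columns:
        series = matrix.data[col].dropna()
        if series.empty:
            continue
        total = series.sum()
        top = series.sort_values(ascending=False, kind="mergesort").head(top_n)
        for rank, (pid, v) in enumerate(top.items(), start=1):
            rows.append({
                "sample": col,
                "rank": rank,
                "protein_id": pid,
                "intensity": float(v),
                "share_percent": 100.0 * float(v) / float(total),
            })
    return pd.DataFrame(rows, columns=["sample", "rank", "protein_id",
                                       "intensity", "share_percent"])


def write_enrichment_report(result: EnrichmentResult, matrix: IntensityMatrix,
                            path) -> None:
    """TSV report: one row per combined-set protein, in ranked order."""
    fg = matrix.fg_intensity()
    with open(path, "w") as fh:
        fh.write("protein_id\tset\tfg_intensity\tcluster\tpc1_loading\n")
        for pid in result.ranking:
            origin = "unique" if pid in result.unique_set else "enriched"
            if pid in result.unique_set and pid in result.enriched_set:
                origin = "both"
            v = fg.get(pid, np.nan)
            cl = result.cluster_labels.get(pid, "")
            ld = result.pca_loadings.get(pid, "")
            fh.write(
                f"{pid}\t{origin}\t"
                f"{'' if not np.isfinite(v) else format(v, 'g')}\t{cl}\t"
                f"{'' if ld == '' else format(ld, '.6g')}\n"
            )
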