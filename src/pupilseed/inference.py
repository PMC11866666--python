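"""Group-level cluster-extent inference on Fisher-z connectivity maps.

Voxel-wise statistics (one-sample t across subjects, or a two-group GLM
with covariates) are thresholded at an uncorrected voxel p < 0.001
(two-sided), suprathreshold voxels are grouped into sign-consistent
face-connected clusters, and each cluster's extent is referred to a
permutation null distribution of maximum cluster extents (sign flips
for the one-sample design, group-label permutation for the group
contrast).  Cluster p-values are then Benjamini-Hochberg corrected and
clusters with FDR-corrected p < 0.05 are declared significant.

The statsmodels-style entry point is :class:`ClusterInferenceModel`,
whose ``fit`` returns a :class:`ClusterInferenceResults` carrying the
stat map, the cluster table and the permutation null, with a
``summary()`` table.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .connectivity import ConnectivityMap

__all__ = [
    "StatMap",
    "Cluster",
    "ClusterTable",
    "NullDistribution",
    "one_sample_t",
    "group_glm",
    "form_clusters",
    "cluster_extent_null",
    "cluster_fdr",
    "label_clusters",
    "ClusterInferenceModel",
    "ClusterInferenceResults",
]


@dataclass
class StatMap:
    """Voxel-wise t statistics for one contrast."""

    t: np.ndarray
    df: int
    contrast: str
    n_subjects: int
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    n_zero_variance: int = 0


@dataclass
class Cluster:
    """A sign-consistent face-connected suprathreshold component."""

    voxels: np.ndarray  # (k, 3) integer indices
    size: int
    peak_voxel: tuple
    peak_mm: tuple
    peak_t: float
    sign: str  # "positive" | "negative"
    p_uncorrected: float = np.nan
    p_fdr: float = np.nan
    name: str = ""

    @property
    def voxel_set(self) -> set:
        return set(map(tuple, self.voxels))


@dataclass
class ClusterTable:
    """Disjoint clusters sorted by extent, with thresholding metadata."""

    clusters: list
    voxel_p: float
    t_threshold: float
    df: int
    connectivity: int = 6
    n_perm: int = 0

    def __post_init__(self) -> None:
        self.clusters = sorted(self.clusters, key=lambda c: -c.size)

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    @property
    def significant(self) -> list:
        return [c for c in self.clusters if np.isfinite(c.p_fdr) and c.p_fdr < 0.05]

    def significant_at(self, q: float) -> list:
        return [c for c in self.clusters if np.isfinite(c.p_fdr) and c.p_fdr < q]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            rows.append(
                {
                    "name": c.name,
                    "peak_x_mm": c.peak_mm[0],
                    "peak_y_mm": c.peak_mm[1],
                    "peak_z_mm": c.peak_mm[2],
                    "size": c.size,
                    "peak_t": c.peak_t,
                    "p_unc": c.p_uncorrected,
                    "p_fdr": c.p_fdr,
                    "sign": c.sign,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "name", "peak_x_mm", "peak_y_mm", "peak_z_mm",
                "size", "peak_t", "p_unc", "p_fdr", "sign",
            ],
        )

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass
class NullDistribution:
    """Permutation null of maximum cluster extent."""

    max_extents: np.ndarray
    n_perm: int
    design: str
    exhaustive: bool = False
    seed: int | None = None


# ---------------------------------------------------------------------------
# stacking helpers


def _stack(zmaps) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_subjects, n_voxels) matrix plus shared mask and affine."""
    if isinstance(zmaps, np.ndarray):
        raise TypeError("pass a list of ConnectivityMap, or use the array API")
    mask = zmaps[0].mask
    affine = zmaps[0].affine
    for m in zmaps[1:]:
        if m.mask.shape != mask.shape or not np.array_equal(m.mask, mask):
            raise ValueError("all maps must share the same mask/grid")
    Z = np.stack([m.masked_z() for m in zmaps])
    return Z, mask, affine


def _as_matrix(zmaps, mask=None, affine=None):
    if isinstance(zmaps, np.ndarray):
        if mask is None:
            raise ValueError("mask required with an array of z values")
        return np.asarray(zmaps, dtype=float), np.asarray(mask, dtype=bool), (
            np.eye(4) if affine is None else affine
        )
    return _stack(zmaps)


# ---------------------------------------------------------------------------
# voxel-wise statistics


def one_sample_t(zmaps, mask=None, affine=None) -> StatMap:
    """Per-voxel one-sample t across subjects: mean / (sd / sqrt(n)),
    df = n - 1.  Voxels with zero between-subject variance get a signed
    infinite sentinel (0 when the mean is also 0) and are counted."""
    Z, mask, affine = _as_matrix(zmaps, mask, affine)
    n = Z.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    mean = Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=1)
    zero = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t_vec = mean / (sd / np.sqrt(n))
    t_vec[zero] = np.sign(mean[zero]) * np.inf
    t_vec[zero & (mean == 0)] = 0.0
    t = np.full(mask.shape, np.nan)
    t[mask] = t_vec
    return StatMap(
        t=t, df=n - 1, contrast="one_sample", n_subjects=n,
        mask=mask, affine=affine, n_zero_variance=int(zero.sum()),
    )


def _group_design(group: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    g = np.asarray(group, dtype=float)
    if np.ptp(g) == 0:
        raise ValueError("group labels are constant")
    cols = [np.ones_like(g), g - g.mean()]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != g.size:
            C = C.T
        C = C - C.mean(axis=0)
        varying = C.std(axis=0) > 0
        if not varying.all():
            warnings.warn(
                "dropping constant covariate column(s) from the group design",
                stacklevel=3,
            )
        if varying.any():
            cols.append(C[:, varying])
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("group design is rank deficient")
    return X


def _glm_t(X: np.ndarray, Y: np.ndarray, col: int = 1) -> tuple[np.ndarray, int]:
    """t statistic for design column ``col``, vectorised over the
    columns of Y (n_subjects, n_voxels)."""
    n, k = X.shape
    df = n - k
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    rss = (resid ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(XtX_inv[col, col] * rss / df)
        t = np.where(se > 0, beta[col] / np.where(se > 0, se, 1.0), 0.0)
    return t, df


def group_glm(zmaps, group, covariates=None, mask=None, affine=None) -> StatMap:
    """Per-voxel OLS of z on [intercept, group, centred covariates];
    returns the t map for the group contrast (group coded so that a
    positive t means higher connectivity in the group coded 1)."""
    Z, mask, affine = _as_matrix(zmaps, mask, affine)
    X = _group_design(group, covariates)
    t_vec, df = _glm_t(X, Z)
    t = np.full(mask.shape, np.nan)
    t[mask] = t_vec
    return StatMap(
        t=t, df=df, contrast="group", n_subjects=Z.shape[0],
        mask=mask, affine=affine,
    )


# ---------------------------------------------------------------------------
# cluster forming


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _max_extent(supra_pos: np.ndarray, supra_neg: np.ndarray, structure) -> int:
    best = 0
    for supra in (supra_pos, supra_neg):
        if supra.any():
            lab, nlab = ndimage.label(supra, structure=structure)
            if nlab:
                counts = np.bincount(lab.ravel())[1:]
                best = max(best, int(counts.max()))
    return best


def form_clusters(
    stat: StatMap, voxel_p: float = 0.001, connectivity: int = 6
) -> ClusterTable:
    """Threshold |t| at the two-sided critical value for ``voxel_p`` and
    group suprathreshold voxels into sign-consistent connected
    components (6-face connectivity by default).  Positive and negative
    components never merge."""
    if stat.df < 1:
        raise ValueError("need df >= 1")
    structure = _STRUCTURES[connectivity]
    t_crit = float(sp_stats.t.isf(voxel_p / 2.0, stat.df))
    t = np.where(stat.mask, stat.t, 0.0)
    clusters = []
    for sign, supra in (("positive", t > t_crit), ("negative", t < -t_crit)):
        if not supra.any():
            continue
        lab, nlab = ndimage.label(supra, structure=structure)
        for i in range(1, nlab + 1):
            vox = np.argwhere(lab == i)
            tvals = t[tuple(vox.T)]
            peak_idx = int(np.argmax(np.abs(tvals)))
            peak_voxel = tuple(int(v) for v in vox[peak_idx])
            peak_mm = tuple(
                float(x) for x in (stat.affine @ np.array([*peak_voxel, 1.0]))[:3]
            )
            clusters.append(
                Cluster(
                    voxels=vox,
                    size=int(vox.shape[0]),
                    peak_voxel=peak_voxel,
                    peak_mm=peak_mm,
                    peak_t=float(tvals[peak_idx]),
                    sign=sign,
                )
            )
    return ClusterTable(
        clusters=clusters, voxel_p=voxel_p, t_threshold=t_crit,
        df=stat.df, connectivity=connectivity,
    )


# ---------------------------------------------------------------------------
# permutation null and FDR


def cluster_extent_null(
    zmaps,
    *,
    design: str = "one_sample",
    group=None,
    covariates=None,
    n_perm: int = 1000,
    seed: int | None = None,
    voxel_p: float = 0.001,
    connectivity: int = 6,
    mask=None,
) -> NullDistribution:
    """Permutation distribution of the maximum cluster extent under the
    null.

    One-sample design: subject maps are randomly sign-flipped (assumes a
    symmetric subject-level null); when all 2^n sign patterns number no
    more than ``n_perm`` they are enumerated exhaustively (with a
    warning).  Group design: group labels are permuted while covariates
    stay attached to their subjects.  Each permutation recomputes the
    voxel statistic, forms clusters at ``voxel_p`` and records the
    maximum extent over both signs (0 when nothing is suprathreshold).
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    Z, mask, _ = _as_matrix(zmaps, mask)
    n, V = Z.shape
    structure = _STRUCTURES[connectivity]
    rng = np.random.default_rng(seed)
    supra_pos = np.zeros(mask.shape, dtype=bool)
    supra_neg = np.zeros(mask.shape, dtype=bool)

    if design == "one_sample":
        df = n - 1
        t_crit = float(sp_stats.t.isf(voxel_p / 2.0, df))
        exhaustive = 2 ** n <= n_perm
        if exhaustive:
            warnings.warn(
                f"only 2^{n} = {2 ** n} distinct sign patterns; "
                "enumerating exhaustively",
                stacklevel=2,
            )
            S = np.array(list(itertools.product((-1.0, 1.0), repeat=n)))
        else:
            S = rng.choice((-1.0, 1.0), size=(n_perm, n))
        ss = (Z ** 2).sum(axis=0)  # invariant under sign flips
        extents = np.empty(S.shape[0], dtype=int)
        for p in range(S.shape[0]):
            m = (S[p] @ Z) / n
            var = (ss - n * m ** 2) / (n - 1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t_vec = m / np.sqrt(var / n)
            t_vec[~np.isfinite(t_vec)] = 0.0
            supra_pos[mask] = t_vec > t_crit
            supra_neg[mask] = t_vec < -t_crit
            extents[p] = _max_extent(supra_pos, supra_neg, structure)
        return NullDistribution(
            max_extents=extents, n_perm=len(extents), design=design,
            exhaustive=exhaustive, seed=seed,
        )

    if design == "group":
        if group is None:
            raise ValueError("group labels required for the group design")
        group = np.asarray(group)
        df = None
        t_crit = None
        extents = np.empty(n_perm, dtype=int)
        for p in range(n_perm):
            X = None
            for _ in range(100):  # redraw when a permuted design degenerates
                perm = rng.permutation(n)
                try:
                    X = _group_design(group[perm], covariates)
                    break
                except ValueError:
                    continue
            if X is None:
                raise ValueError("could not draw a full-rank permuted design")
            t_vec, df = _glm_t(X, Z)
            if t_crit is None:
                t_crit = float(sp_stats.t.isf(voxel_p / 2.0, df))
            t_vec = np.where(np.isfinite(t_vec), t_vec, 0.0)
            supra_pos[mask] = t_vec > t_crit
            supra_neg[mask] = t_vec < -t_crit
            extents[p] = _max_extent(supra_pos, supra_neg, structure)
        return NullDistribution(
            max_extents=extents, n_perm=n_perm, design=design, seed=seed
        )

    raise ValueError(f"unknown design {design!r}")


def cluster_fdr(
    table: ClusterTable, null: NullDistribution, q: float = 0.05
) -> ClusterTable:
    """Attach permutation cluster p-values and BH-FDR corrected p-values.

    p_uncorrected = (1 + #{null max extents >= size}) / (n_perm + 1);
    Benjamini-Hochberg is applied across every cluster in the table.
    """
    if null.max_extents.size == 0:
        raise ValueError("empty null distribution")
    ext = np.sort(null.max_extents)
    m = ext.size
    clusters = []
    for c in table.clusters:
        n_ge = m - np.searchsorted(ext, c.size, side="left")
        p = (1.0 + n_ge) / (m + 1.0)
        clusters.append(replace(c, p_uncorrected=float(p)))
    if clusters:
        pvals = np.array([c.p_uncorrected for c in clusters])
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        clusters = [replace(c, p_fdr=float(qv)) for c, qv in zip(clusters, qvals)]
    return ClusterTable(
        clusters=clusters, voxel_p=table.voxel_p, t_threshold=table.t_threshold,
        df=table.df, connectivity=table.connectivity, n_perm=m,
    )


# ---------------------------------------------------------------------------
# anatomical labelling


def label_clusters(
    table: ClusterTable, label_volume: np.ndarray, names: dict
) -> ClusterTable:
    """Name each cluster from an integer label volume: the peak voxel's
    label; if the peak is unlabeled (0), the majority label among its 26
    neighbours with '*' appended; if those are unlabeled too,
    'unlabeled*'."""
    label_volume = np.asarray(label_volume)
    clusters = []
    for c in table.clusters:
        if label_volume.ndim != 3:
            raise ValueError("label volume must be 3-D")
        try:
            lab = int(label_volume[c.peak_voxel])
        except IndexError as exc:
            raise ValueError("label volume grid does not match stat grid") from exc
        if lab != 0:
            name = names.get(lab, str(lab))
        else:
            neigh = []
            for di, dj, dk in itertools.product((-1, 0, 1), repeat=3):
                if di == dj == dk == 0:
                    continue
                i, j, k = (
                    c.peak_voxel[0] + di,
                    c.peak_voxel[1] + dj,
                    c.peak_voxel[2] + dk,
                )
                if (
                    0 <= i < label_volume.shape[0]
                    and 0 <= j < label_volume.shape[1]
                    and 0 <= k < label_volume.shape[2]
                ):
                    v = int(label_volume[i, j, k])
                    if v != 0:
                        neigh.append(v)
            if neigh:
                vals, counts = np.unique(neigh, return_counts=True)
                best = int(vals[np.argmax(counts)])
                name = names.get(best, str(best)) + "*"
            else:
                name = "unlabeled*"
        clusters.append(replace(c, name=name))
    return ClusterTable(
        clusters=clusters, voxel_p=table.voxel_p, t_threshold=table.t_threshold,
        df=table.df, connectivity=table.connectivity, n_perm=table.n_perm,
    )


# ---------------------------------------------------------------------------
# Model / Results


class ClusterInferenceModel:
    """Group-level cluster-extent inference on a stack of Fisher-z maps.

    Parameters
    ----------
    zmaps : list of ConnectivityMap, or (n_subjects, n_voxels) array
        Subject-level Fisher-z maps on a shared grid.
    group : array-like of {0, 1}, optional
        When given, the model tests the group contrast in a GLM with
        the centred covariates; otherwise a one-sample test.
    covariates : array-like, optional
        Per-subject covariate columns (e.g. sex), centred internally.
    mask, affine : required only with the array form of ``zmaps``.
    """

    def __init__(self, zmaps, group=None, covariates=None, mask=None, affine=None):
        self.Z, self.mask, self.affine = _as_matrix(zmaps, mask, affine)
        self.group = None if group is None else np.asarray(group)
        self.covariates = covariates
        self.design = "one_sample" if group is None else "group"

    def fit(
        self,
        voxel_p: float = 0.001,
        n_perm: int = 1000,
        q: float = 0.05,
        seed: int | None = None,
        connectivity: int = 6,
    ) -> "ClusterInferenceResults":
        """Run the voxel statistic, cluster forming, permutation null
        and FDR correction; returns a results object."""
        if self.design == "one_sample":
            stat = one_sample_t(self.Z, mask=self.mask, affine=self.affine)
        else:
            stat = group_glm(
                self.Z, self.group, self.covariates,
                mask=self.mask, affine=self.affine,
            )
        table = form_clusters(stat, voxel_p=voxel_p, connectivity=connectivity)
        null = cluster_extent_null(
            self.Z, design=self.design, group=self.group,
            covariates=self.covariates, n_perm=n_perm, seed=seed,
            voxel_p=voxel_p, connectivity=connectivity, mask=self.mask,
        )
        table = cluster_fdr(table, null, q=q)
        return ClusterInferenceResults(
            model=self, stat_map=stat, clusters=table, null=null, q=q
        )


@dataclass
class ClusterInferenceResults:
    """Fitted cluster inference: stat map, cluster table, permutation
    null and the FDR level used."""

    model: ClusterInferenceModel
    stat_map: StatMap
    clusters: ClusterTable
    null: NullDistribution
    q: float = 0.05

    @property
    def significant_clusters(self) -> list:
        return self.clusters.significant_at(self.q)

    def summary(self) -> str:
        df = self.clusters.to_dataframe()
        head = (
            f"Cluster-extent inference ({self.stat_map.contrast}), "
            f"n={self.stat_map.n_subjects}, df={self.stat_map.df}\n"
            f"voxel p<{self.clusters.voxel_p} (|t|>{self.clusters.t_threshold:.3f}), "
            f"{self.null.n_perm} permutations"
            f"{' (exhaustive)' if self.null.exhaustive else ''}, "
            f"FDR q<{self.q}\n"
            f"{len(self.clusters)} clusters, "
            f"{len(self.significant_clusters)} significant\n"
        )
        if len(df) == 0:
            return head + "(no suprathreshold clusters)"
        return head + df.to_string(index=False, float_format=lambda v: f"{v:.4g}")
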