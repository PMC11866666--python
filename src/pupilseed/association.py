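"""Cluster-covariate association testing.

For each significant cluster, a per-subject connectivity summary (mean
Fisher z over the cluster's voxels) is related to neuropsychological
scores and CSF analytes by partial correlation with age and sex as
covariates, with Benjamini-Hochberg FDR across the cluster x measure
family.  The identical code path runs on local-correlation maps as the
negative control for seed-mediated effects.  Cohort-level summary
comparisons (pooled two-sample t from printed means/SDs) are also
provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "cluster_summary",
    "summarize_clusters",
    "partial_association",
    "fdr_adjust",
    "two_sample_t_from_summary",
    "run_association_battery",
    "encode_sex",
    "ClusterAssociationModel",
    "ClusterAssociationResults",
]


@dataclass(frozen=True)
class AssociationResult:
    """Partial correlation of one cluster summary with one measure."""

    cluster: str
    measure: str
    partial_r: float
    p: float
    n: int
    covariates: tuple
    p_fdr: float = np.nan
    non_estimable: bool = False


def cluster_summary(zmap, cluster, stat: str = "mean") -> float:
    """Per-subject scalar connectivity for a cluster: mean (default) or
    median Fisher z over the cluster's voxels."""
    vox = np.asarray(cluster.voxels)
    if vox.size == 0:
        raise ValueError("empty cluster")
    z = zmap.z if hasattr(zmap, "z") else zmap.value
    vals = z[tuple(vox.T)]
    if not np.all(np.isfinite(vals)):
        raise ValueError("cluster voxels fall outside the map's mask")
    return float(np.mean(vals) if stat == "mean" else np.median(vals))


def summarize_clusters(zmaps, clusters, stat: str = "mean") -> np.ndarray:
    """(n_subjects, n_clusters) matrix of per-subject cluster summaries."""
    return np.array(
        [[cluster_summary(m, c, stat=stat) for c in clusters] for m in zmaps]
    )


def encode_sex(sex) -> np.ndarray:
    """0/1 encoding of a sex column (accepts 'M'/'F', 'male'/'female',
    or numeric), centred by the caller where needed."""
    s = pd.Series(sex)
    if s.dtype.kind in "ifu":
        return s.to_numpy(dtype=float)
    mapping = {"m": 1.0, "male": 1.0, "f": 0.0, "female": 0.0}
    out = s.astype(str).str.lower().map(mapping)
    if out.isna().any():
        raise ValueError("unrecognised sex codes")
    return out.to_numpy(dtype=float)


def partial_association(y, x, covars, labels=("cluster", "measure")) -> AssociationResult:
    """Partial Pearson correlation of y with x given covariates.

    Both variables are residualised on [intercept | covars]; the partial
    r is the correlation of the residuals and its p-value comes from
    t = r sqrt((n - k - 2) / (1 - r^2)) with k covariates, two-sided.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    C = np.atleast_2d(np.asarray(covars, dtype=float))
    if C.shape[0] != y.size:
        C = C.T
    n = y.size
    k = C.shape[1]
    if n <= k + 2 or n <= 4:
        raise ValueError("too few observations for a partial correlation")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x)) and np.all(np.isfinite(C))):
        raise ValueError("inputs must be complete; apply listwise deletion first")
    X = np.column_stack([np.ones(n), C])
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
    sy, sx = ry.std(), rx.std()
    tol_y = 1e-10 * (np.abs(y).max() + 1.0)
    tol_x = 1e-10 * (np.abs(x).max() + 1.0)
    if sy <= tol_y or sx <= tol_x:
        return AssociationResult(
            cluster=labels[0], measure=labels[1], partial_r=np.nan, p=np.nan,
            n=n, covariates=tuple(range(k)), non_estimable=True,
        )
    r = float(np.clip((ry @ rx) / (n * sy * sx), -1.0, 1.0))
    df = n - k - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sp_stats.t.sf(abs(t), df))
    return AssociationResult(
        cluster=labels[0], measure=labels[1], partial_r=r, p=max(p, np.finfo(float).tiny),
        n=n, covariates=tuple(range(k)),
    )


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def two_sample_t_from_summary(mean1, sd1, n1, mean2, sd2, n2) -> tuple[float, int]:
    """Pooled-variance independent two-sample t from group summary
    statistics; returns (t, df) with t oriented as group2 - group1."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    diff = mean2 - mean1
    if sp2 == 0:
        return (0.0 if diff == 0 else float(np.sign(diff) * np.inf)), df
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), df


def run_association_battery(
    summaries: np.ndarray,
    cluster_names: list,
    pheno: pd.DataFrame,
    measures: list,
    covars: tuple = ("age_years", "sex"),
    summary_stat: str = "mean",
    subject_ids=None,
) -> pd.DataFrame:
    """All cluster x measure partial associations with FDR over the
    whole family.

    ``summaries`` is (n_subjects, n_clusters) in the row order of
    ``pheno``; per measure, subjects with a missing measure or covariate
    are listwise-deleted (counts recorded in the output).  Sex is 0/1
    encoded and centred.
    """
    summaries = np.asarray(summaries, dtype=float)
    if summaries.shape[0] != len(pheno):
        raise ValueError(
            f"subject mismatch: {summaries.shape[0]} summary rows vs "
            f"{len(pheno)} phenotype rows"
        )
    if subject_ids is not None and "id" in pheno.columns:
        bad = [a for a, b in zip(subject_ids, pheno["id"]) if a != b]
        if bad:
            raise ValueError(f"subject id mismatch for: {bad}")
    cov_cols = []
    for c in covars:
        col = encode_sex(pheno[c]) if c == "sex" else pheno[c].to_numpy(dtype=float)
        cov_cols.append(col)
    C = np.column_stack(cov_cols)
    rows = []
    for mi, measure in enumerate(measures):
        x = pheno[measure].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.all(np.isfinite(C), axis=1)
        n_dropped = int((~ok).sum())
        for ci, cname in enumerate(cluster_names):
            y = summaries[:, ci]
            keep = ok & np.isfinite(y)
            try:
                res = partial_association(
                    y[keep], x[keep], C[keep], labels=(str(cname), measure)
                )
            except ValueError:
                res = AssociationResult(
                    cluster=str(cname), measure=measure, partial_r=np.nan,
                    p=np.nan, n=int(keep.sum()), covariates=(),
                    non_estimable=True,
                )
            rows.append(
                {
                    "cluster": res.cluster,
                    "measure": res.measure,
                    "partial_r": res.partial_r,
                    "p": res.p,
                    "n": res.n,
                    "n_dropped": n_dropped,
                    "non_estimable": res.non_estimable,
                }
            )
    out = pd.DataFrame(rows)
    est = ~out["non_estimable"]
    out["p_fdr"] = np.nan
    if est.any():
        out.loc[est, "p_fdr"] = fdr_adjust(out.loc[est, "p"].to_numpy())
    out.attrs["covariates"] = tuple(covars)
    out.attrs["summary_stat"] = summary_stat
    out.attrs["family"] = "all cluster x measure tests in this battery"
    return out


# ---------------------------------------------------------------------------
# Model / Results


class ClusterAssociationModel:
    """Association of per-cluster connectivity with subject measures.

    Parameters
    ----------
    zmaps : list of ConnectivityMap or LocalCorrMap
        Subject maps in the row order of ``pheno``.
    clusters : iterable of Cluster
        Clusters whose mean (or median) map value is the per-subject
        outcome.
    pheno : DataFrame
        Subject phenotypes; must contain the covariate and measure
        columns.
    """

    def __init__(self, zmaps, clusters, pheno: pd.DataFrame, summary_stat="mean"):
        self.clusters = list(clusters)
        self.pheno = pheno.reset_index(drop=True)
        self.summary_stat = summary_stat
        self.summaries = summarize_clusters(zmaps, self.clusters, stat=summary_stat)
        if self.summaries.shape[0] != len(self.pheno):
            raise ValueError("subject count mismatch between maps and phenotypes")

    def fit(
        self,
        measures: list,
        covars: tuple = ("age_years", "sex"),
        q: float = 0.05,
    ) -> "ClusterAssociationResults":
        names = [c.name or f"cluster_{i}" for i, c in enumerate(self.clusters)]
        table = run_association_battery(
            self.summaries, names, self.pheno, measures,
            covars=covars, summary_stat=self.summary_stat,
            subject_ids=self.pheno.get("id"),
        )
        return ClusterAssociationResults(model=self, table=table, q=q)


@dataclass
class ClusterAssociationResults:
    model: ClusterAssociationModel
    table: pd.DataFrame
    q: float = 0.05

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["p_fdr"] < self.q]

    def summary(self) -> str:
        head = (
            f"Cluster-measure partial correlations "
            f"(covariates: {', '.join(self.table.attrs['covariates'])}), "
            f"BH-FDR q<{self.q}\n"
            f"{len(self.table)} tests, {len(self.significant)} significant\n"
        )
        cols = ["cluster", "measure", "partial_r", "p", "p_fdr", "n"]
        return head + self.table[cols].to_string(
            index=False, float_format=lambda v: f"{v:.4g}"
        )
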