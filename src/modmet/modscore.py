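"""Rank-based differential scoring of genes and functional modules.

The scoring pipeline compares two phenotype groups of a quantile-normalized
expression matrix with the Mann-Whitney U statistic.  Each gene receives a
sample-size-adjusted *gene score*

    score_i = (U1_i - U2_i) / (n1 + n2) = (2 U1_i - n1 n2) / (n1 + n2),

where ``U1`` is the U statistic of the case group, ``U2 = n1 n2 - U1`` that of
the control group, and ``n1``/``n2`` the group sizes.  The score lies in
``[-n1 n2/(n1+n2), +n1 n2/(n1+n2)]`` and is comparable across cohorts of
different sizes.  A *functional module* (gene set) is scored by the median of
its member gene scores, and module significance is assessed by a pooled
label-permutation false-discovery-rate estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionDataset",
    "GroupComparison",
    "quantile_normalize",
    "u_statistics",
    "gene_score",
    "score_all_genes",
    "module_scores",
    "permutation_fdr",
    "module_plane",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """Genes x samples abundance matrix with per-sample phenotype labels.

    Parameters
    ----------
    gene_ids, sample_ids
        Unique identifiers for the matrix rows / columns.
    values
        Abundance matrix of shape ``(n_genes, n_samples)``.  Interpreted as
        log2-scale when ``log2`` is true (the default), which only affects
        fold-change computation.
    labels
        Mapping sample id -> group label; every sample must be labelled.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: dict[str, str]
    log2: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = pd.Index(self.gene_ids)
            raise ValueError(
                f"duplicate gene ids: {sorted(dup[dup.duplicated()].unique())[:5]}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        missing = [s for s in self.sample_ids if s not in self.labels]
        if missing:
            raise ValueError(f"samples without labels: {missing[:5]}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def group_columns(self, label: str) -> np.ndarray:
        """Column indices of the samples carrying ``label``."""
        idx = [j for j, s in enumerate(self.sample_ids) if self.labels[s] == label]
        return np.asarray(idx, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class GroupComparison:
    """A two-group contrast: ``case_label`` (n1) versus ``control_label`` (n2)."""

    case_label: str
    control_label: str

    def __post_init__(self) -> None:
        if self.case_label == self.control_label:
            raise ValueError("case and control labels must differ")

    @property
    def name(self) -> str:
        return f"{self.case_label}_vs_{self.control_label}"


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(dataset: ExpressionDataset) -> ExpressionDataset:
    """Force every sample column onto the common per-rank mean distribution.

    After normalization each column holds the same sorted value multiset: the
    mean over input columns of the k-th smallest value, for each rank k.
    Within-column rank order is preserved; tied values within a column receive
    the mean of the reference values spanning their tied ranks.
    """
    values = dataset.values
    if values.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    reference = np.sort(values, axis=0).mean(axis=1)
    # cumulative sums let a tied block [rmin, rmax] average in O(1)
    csum = np.concatenate([[0.0], np.cumsum(reference)])
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        rmin = stats.rankdata(col, method="min").astype(int)
        rmax = stats.rankdata(col, method="max").astype(int)
        out[:, j] = (csum[rmax] - csum[rmin - 1]) / (rmax - rmin + 1)
    return replace(dataset, values=out)


# ---------------------------------------------------------------------------
# U statistics and gene scores
# ---------------------------------------------------------------------------

def _u1_from_ranks(ranks: np.ndarray, case_cols: np.ndarray, n1: int) -> np.ndarray:
    """U1 per gene from mid-ranks of the combined two-group submatrix."""
    return ranks[:, case_cols].sum(axis=1) - n1 * (n1 + 1) / 2.0


def _tie_term(sub: np.ndarray) -> np.ndarray:
    """Per-gene tie correction sum(t^3 - t) over tied groups of each row."""
    srt = np.sort(sub, axis=1)
    out = np.zeros(sub.shape[0])
    for i in range(sub.shape[0]):
        _, counts = np.unique(srt[i], return_counts=True)
        t = counts[counts > 1].astype(float)
        out[i] = np.sum(t**3 - t)
    return out

def _u_pvalues(u1: np.ndarray, n1: int, n2: int, tie: np.ndarray) -> np.ndarray:
    """Two-sided normal-approximation p with tie and continuity correction."""
    n = n1 + n2
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1.0)))
    p = np.ones_like(np.asarray(u1, dtype=float))
    ok = var > 0
    z = np.maximum(np.abs(np.asarray(u1, float)[ok] - mu) - 0.5, 0.0) / np.sqrt(var[ok])
    p[ok] = np.minimum(1.0, 2.0 * stats.norm.sf(z))
    return p


def u_statistics(case_values, control_values) -> tuple[float, float, float]:
    """Mann-Whitney U for one gene: returns ``(u1, u2, p_two_sided)``.

    ``u1`` counts case/control pairs where the case value is larger, with half
    credit for ties; ``u2 = n1*n2 - u1``.  The p-value uses the tie-corrected
    normal approximation with continuity correction.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = case.size, control.size
    combined = np.concatenate([case, control])[None, :]
    ranks = stats.rankdata(combined, axis=1)
    u1 = float(_u1_from_ranks(ranks, np.arange(n1), n1)[0])
    p = float(_u_pvalues(np.array([u1]), n1, n2, _tie_term(combined))[0])
    return u1, n1 * n2 - u1, p


def gene_score(u1: float, n1: int, n2: int) -> float:
    """Sample-size-adjusted gene score ``(2*u1 - n1*n2) / (n1 + n2)``."""
    if not 0 <= u1 <= n1 * n2:
        raise ValueError(f"u1={u1} outside [0, {n1 * n2}]")
    return (2.0 * u1 - n1 * n2) / (n1 + n2)


def score_all_genes(
    dataset: ExpressionDataset, comparison: GroupComparison
) -> pd.DataFrame:
    """Score every gene for one two-group comparison.

    Returns a DataFrame indexed by gene id with columns ``u1``, ``u2``,
    ``score``, ``p_value`` and ``fold_change`` (case mean over control mean on
    the linear scale; values are exponentiated first when the dataset is
    flagged log2).
    """
    case_cols = dataset.group_columns(comparison.case_label)
    ctrl_cols = dataset.group_columns(comparison.control_label)
    n1, n2 = case_cols.size, ctrl_cols.size
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"comparison {comparison.name} needs >=2 samples per group "
            f"(got n1={n1}, n2={n2})"
        )
    sub = dataset.values[:, np.concatenate([case_cols, ctrl_cols])]
    ranks = stats.rankdata(sub, axis=1)
    u1 = _u1_from_ranks(ranks, np.arange(n1), n1)
    p = _u_pvalues(u1, n1, n2, _tie_term(sub))
    score = (2.0 * u1 - n1 * n2) / (n1 + n2)

    lin = np.power(2.0, dataset.values) if dataset.log2 else dataset.values
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = lin[:, case_cols].mean(axis=1) / lin[:, ctrl_cols].mean(axis=1)
    return pd.DataFrame(
        {
            "u1": u1,
            "u2": n1 * n2 - u1,
            "score": score,
            "p_value": p,
            "fold_change": fc,
        },
        index=pd.Index(dataset.gene_ids, name="gene_id"),
    )


# ---------------------------------------------------------------------------
# Module scores and permutation FDR
# ---------------------------------------------------------------------------

def module_scores(
    records: pd.DataFrame,
    modules: dict[str, list[str]],
    min_genes: int = 3,
) -> pd.DataFrame:
    """Median gene score per module.

    Modules with fewer than ``min_genes`` member genes found in ``records``
    are dropped with a warning.  Returns a DataFrame indexed by module id with
    ``n_genes_found`` and ``module_score``.
    """
    rows = {}
    for mod_id, genes in modules.items():
        present = records.index.intersection(pd.unique(pd.Series(list(genes))))
        if len(present) < min_genes:
            warnings.warn(
                f"module {mod_id!r} dropped: {len(present)} gene(s) found "
                f"(min_genes={min_genes})",
                stacklevel=2,
            )
            continue
        rows[mod_id] = {
            "n_genes_found": len(present),
            "module_score": float(records.loc[present, "score"].median()),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "module_id"
    return out


def _permutation_scores(
    dataset: ExpressionDataset,
    comparison: GroupComparison,
    module_index: dict[str, np.ndarray],
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null module scores, shape (n_perm, n_modules).

    Labels are shuffled only among the samples of the two compared groups;
    ranks of the combined submatrix are computed once since a label
    permutation only reassigns which columns count as case.
    """
    case_cols = dataset.group_columns(comparison.case_label)
    ctrl_cols = dataset.group_columns(comparison.control_label)
    n1, n2 = case_cols.size, ctrl_cols.size
    sub = dataset.values[:, np.concatenate([case_cols, ctrl_cols])]
    ranks = stats.rankdata(sub, axis=1)
    n_modules = len(module_index)
    null = np.empty((n_perm, n_modules))
    for b in range(n_perm):
        perm = rng.permutation(n1 + n2)
        u1 = _u1_from_ranks(ranks, perm[:n1], n1)
        scores = (2.0 * u1 - n1 * n2) / (n1 + n2)
        for k, gidx in enumerate(module_index.values()):
            null[b, k] = np.median(scores[gidx])
    return null


def permutation_fdr(
    dataset: ExpressionDataset,
    comparison: GroupComparison,
    modules: dict[str, list[str]],
    n_perm: int = 100,
    seed: int = 0,
    fdr_threshold: float = 0.05,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Module scores with pooled label-permutation FDR.

    For module *m* with observed absolute score ``s_m`` the plug-in estimate is

        FDR(m) = E_perm[ #{modules with |null score| >= s_m} ]
                 / #{modules with |observed score| >= s_m},

    clipped to [0, 1] and made monotone (a module with a larger absolute
    score never receives a larger FDR) by a running minimum down the score
    ordering, as in q-value step-up enforcement.  ``significant`` flags
    ``fdr < fdr_threshold``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    records = score_all_genes(dataset, comparison)
    observed = module_scores(records, modules, min_genes=min_genes)
    if observed.empty:
        raise ValueError("no scoreable modules (all dropped by min_genes)")

    gene_pos = {g: i for i, g in enumerate(dataset.gene_ids)}
    module_index = {
        mod_id: np.asarray(
            [gene_pos[g] for g in dict.fromkeys(modules[mod_id]) if g in gene_pos],
            dtype=int,
        )
        for mod_id in observed.index
    }
    rng = np.random.default_rng(seed)
    null = np.abs(
        _permutation_scores(dataset, comparison, module_index, n_perm, rng)
    )

    s = np.abs(observed["module_score"].to_numpy())
    # pooled counts: for each s_m, mean over permutations of null exceedances
    num = (null[:, :, None] >= s[None, None, :]).sum(axis=1).mean(axis=0)
    den = (s[:, None] >= s[None, :]).sum(axis=0)
    fdr = np.clip(num / den, 0.0, 1.0)
    # enforce monotonicity in |score|: each module takes the min of its own
    # estimate and those of all less extreme modules (q-value step-up)
    order = np.argsort(-s, kind="stable")
    fdr[order] = np.minimum.accumulate(fdr[order][::-1])[::-1]

    out = observed.copy()
    out["fdr"] = fdr
    out["significant"] = out["fdr"] < fdr_threshold
    return out


def module_plane(
    dataset: ExpressionDataset,
    comparisons: tuple[GroupComparison, GroupComparison],
    modules: dict[str, list[str]],
    n_perm: int = 100,
    seed: int = 0,
    fdr_threshold: float = 0.05,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Two-comparison module plane: one score axis per comparison, min FDR.

    Used for scatter export of modules over, e.g., (normal vs early) x
    (early vs late).  Seeds for the two permutation runs are derived from
    ``seed`` deterministically.
    """
    results = []
    for k, comp in enumerate(comparisons):
        res = permutation_fdr(
            dataset, comp, modules, n_perm=n_perm, seed=seed + k,
            fdr_threshold=fdr_threshold, min_genes=min_genes,
        )
        results.append(res.rename(columns={
            "module_score": f"score_{comp.name}", "fdr": f"fdr_{comp.name}",
        })[[f"score_{comp.name}", f"fdr_{comp.name}"]])
    plane = results[0].join(results[1], how="outer")
    plane["fdr_min"] = plane[[c for c in plane.columns if c.startswith("fdr_")]].min(
        axis=1
    )
    return plane
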