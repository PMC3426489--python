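"""Pathway enrichment of dysregulated pairwise interactions.

For each pathway P and profile kind, every unordered gene pair is scored
with a two-sample t-statistic Z_ij of its interaction profile between case
and control samples.  The pathway summary is the *maxmean* statistic

    S(P) = max( mean of positive Z_ij , |mean of negative Z_ij| )

which is sensitive to unusually large pair scores in either or both
directions.  Significance comes from a permutation test: sample labels are
shuffled B times (class sizes preserved), S is recomputed each time, S is
standardized by the mean/SD of this permutation null catalog, and the
p-value is the fraction of permuted statistics at least as large as the
observed one.  Because the permutation test is stochastic, the whole
procedure is repeated over several independent runs and the run p-values
averaged.  Finally the p-values of all pathways (per kind) are converted
to Storey q-values.

One label shuffle per replicate scores every pathway (the marginal null of
each pathway is unchanged, and the shared draws make the test dramatically
cheaper).  When the number of distinct label assignments C(m, n_case) does
not exceed B, the exact enumeration replaces random sampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from .errors import ValidationError
from .io import ExpressionDataset, GeneSetCollection
from .profiles import ProfileKind, profile_matrix, two_sample_t

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentConfig",
    "maxmean",
    "standardize_statistic",
    "qvalues",
    "permutation_pvalue",
    "run_enrichment",
]


@dataclass(frozen=True)
class EnrichmentConfig:
    """Tunable parameters of the enrichment procedure.

    B
        permutations per run (default 5000).
    runs
        independent permutation runs whose p-values are averaged
        (default 4).
    seed
        master seed; each run draws from an independent substream.
    q_threshold
        q-value at or below which a pathway is called dysregulated
        (default 0.01).
    min_genes / max_genes
        pathway size filter applied after intersecting with the dataset.
    equal_var
        pooled-variance t-statistic (default) vs Welch.
    standardization
        ``"permutation"`` (default): standardize each pathway's maxmean by
        the mean/SD of its own permutation null catalog.  ``"pooled_pairs"``:
        standardize by the mean/SD of all observed pair scores pooled
        across pathways.  Both are monotone transforms shared by observed
        and permuted statistics, so the permutation p-value is identical.
    smooth_pvalues
        if True use (count + 1)/(B + 1) instead of count/B.
    exact_when_possible
        enumerate all label assignments when C(m, n_case) <= B.
    """

    B: int = 5000
    runs: int = 4
    seed: int = 0
    q_threshold: float = 0.01
    min_genes: int = 2
    max_genes: int | None = None
    equal_var: bool = True
    standardization: str = "permutation"
    smooth_pvalues: bool = False
    exact_when_possible: bool = True

    def __post_init__(self) -> None:
        if self.B < 100:
            raise ValidationError(f"B must be >= 100, got {self.B}")
        if self.runs < 1:
            raise ValidationError(f"runs must be >= 1, got {self.runs}")
        if self.standardization not in ("permutation", "pooled_pairs"):
            raise ValidationError(
                f"unknown standardization {self.standardization!r}"
            )


# ---------------------------------------------------------------------------
# the maxmean statistic
# ---------------------------------------------------------------------------

def maxmean(z_values) -> float:
    """Larger of the mean positive part and |mean negative part|.

    Zeros belong to neither part; an empty part contributes 0 to the
    comparison.  Always non-negative.
    """
    z = np.asarray(z_values, dtype=float)
    if z.size == 0:
        raise ValidationError("maxmean needs a non-empty score list")
    pos = z[z > 0]
    neg = z[z < 0]
    pos_mean = pos.sum() / pos.size if pos.size else 0.0
    neg_mean = -neg.sum() / neg.size if neg.size else 0.0
    return float(max(pos_mean, neg_mean))


def _maxmean_columns(T: np.ndarray) -> np.ndarray:
    """maxmean of each column of a (pairs x B) score matrix, vectorized."""
    pos = np.where(T > 0, T, 0.0)
    neg = np.where(T < 0, T, 0.0)
    n_pos = (T > 0).sum(axis=0)
    n_neg = (T < 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pos_mean = np.where(n_pos > 0, pos.sum(axis=0) / np.maximum(n_pos, 1), 0.0)
        neg_mean = np.where(n_neg > 0, -neg.sum(axis=0) / np.maximum(n_neg, 1), 0.0)
    return np.maximum(pos_mean, neg_mean)


def standardize_statistic(raw_S: float, null_catalog) -> tuple[float, bool]:
    """(raw_S - mean(catalog)) / sd(catalog); flag True when sd == 0.

    The catalog is the permutation null of the same statistic (or, under
    the pooled-pairs convention, the pooled pair scores).  Sample standard
    deviation (ddof=1) is used.
    """
    catalog = np.asarray(null_catalog, dtype=float)
    if catalog.size < 2:
        raise ValidationError("null catalog needs >= 2 values")
    mu = catalog.mean()
    sd = catalog.std(ddof=1)
    if sd == 0.0:
        return 0.0, True
    return float((raw_S - mu) / sd), False


# ---------------------------------------------------------------------------
# q-values (Storey FDR)
# ---------------------------------------------------------------------------

def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (n (1 - lambda)) is computed over a
    lambda grid and smoothed with a cubic fit (the df = 3 smoothing-spline
    approximation); the fitted value at the largest lambda is the
    estimate, clipped to (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    lambdas = np.asarray(lambdas, dtype=float)
    pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    if np.all(pi0_l == 0):
        return 1.0 / len(p)  # every p-value beyond every lambda: tiny pi0
    if len(lambdas) >= 4:
        coef = np.polyfit(lambdas, pi0_l, 3)
        pi0 = float(np.polyval(coef, lambdas[-1]))
    else:  # grid too short to smooth
        pi0 = float(pi0_l[-1])
    return float(min(max(pi0, 1.0 / len(p)), 1.0))


def qvalues(
    p_values,
    *,
    pi0: float | None = None,
    min_n_for_pi0: int = 50,
    lambdas: np.ndarray | None = None,
) -> np.ndarray:
    """Storey q-values of a p-value list (order preserved).

    q_(i) = pi0 * n * p_(i) / i with monotonicity enforced from the
    largest p-value downwards.  With ``pi0=1`` this is exactly the
    Benjamini-Hochberg adjusted p-value.  pi0 estimation is unstable for
    short lists, so lists shorter than ``min_n_for_pi0`` fall back to
    pi0 = 1 (logged).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if pi0 is None:
        if p.size < min_n_for_pi0:
            log.info("only %d p-values; using pi0 = 1 (BH)", p.size)
            pi0 = 1.0
        else:
            pi0 = estimate_pi0(p, lambdas)
    if not 0 < pi0 <= 1:
        raise ValidationError(f"pi0 must be in (0, 1], got {pi0}")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * n * ranked / np.arange(1, n + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def _permutation_masks(
    m: int, n_case: int, B: int, rng: np.random.Generator, exact_when_possible: bool
) -> tuple[np.ndarray, bool]:
    """(B x m) boolean case-assignment matrix; exact enumeration if small.

    Returns (masks, exact).  Exact enumeration yields all C(m, n_case)
    distinct assignments (its size replaces B).
    """
    total = comb(m, n_case)
    if exact_when_possible and total <= B:
        if total < B:
            log.warning(
                "only %d distinct label assignments exist (< B = %d); "
                "using exact enumeration", total, B,
            )
        masks = np.zeros((total, m), dtype=bool)
        for r, idx in enumerate(combinations(range(m), n_case)):
            masks[r, list(idx)] = True
        return masks, True
    masks = np.zeros((B, m), dtype=bool)
    for r in range(B):
        masks[r, rng.choice(m, size=n_case, replace=False)] = True
    return masks, False


def _tstat_matrix(
    V: np.ndarray, masks: np.ndarray, equal_var: bool = True
) -> np.ndarray:
    """t-statistics of each profile row under each label assignment.

    ``V`` is (pairs x m), ``masks`` is (B x m) boolean; returns (pairs x B).
    Implemented with two matrix products over group sums and sums of
    squares, which is what makes sharing permutations across pathways
    cheap.  Rows with zero pooled variance under a given assignment score 0.
    """
    V = np.asarray(V, dtype=float)
    L = masks.T.astype(float)  # (m x B)
    m = V.shape[1]
    n1 = int(masks[0].sum())
    n0 = m - n1
    tot = V.sum(axis=1, keepdims=True)
    totq = (V**2).sum(axis=1, keepdims=True)
    S1 = V @ L
    Q1 = (V**2) @ L
    mean1 = S1 / n1
    mean0 = (tot - S1) / n0
    ss1 = np.maximum(Q1 - S1**2 / n1, 0.0)
    ss0 = np.maximum((totq - Q1) - (tot - S1) ** 2 / n0, 0.0)
    if equal_var:
        sp2 = (ss1 + ss0) / (n1 + n0 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    else:
        se = np.sqrt(ss1 / (n1 * (n1 - 1)) + ss0 / (n0 * (n0 - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (mean1 - mean0) / se
    T[~np.isfinite(T)] = 0.0
    return T


def _run_seed_rng(seed: int, run: int) -> np.random.Generator:
    """Independent substream per run, derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(run,)))


def permutation_pvalue(
    ds: ExpressionDataset,
    pathway_genes,
    kind: ProfileKind | str,
    cfg: EnrichmentConfig,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Standardized maxmean S and one-run permutation p for one pathway."""
    kind = ProfileKind.coerce(kind)
    if rng is None:
        rng = _run_seed_rng(cfg.seed, 0)
    genes = sorted(set(g.upper() for g in pathway_genes) & set(ds.genes))
    if len(genes) < max(cfg.min_genes, 2):
        raise ValidationError(
            f"pathway matches {len(genes)} gene(s); need >= {max(cfg.min_genes, 2)}"
        )
    idx = [ds.gene_index[g] for g in genes]
    V, _, _ = profile_matrix(ds.values[idx], kind)
    masks, _ = _permutation_masks(
        len(ds.samples), ds.n_case, cfg.B, rng, cfg.exact_when_possible
    )
    z_obs = two_sample_t(V, ds.case_mask, equal_var=cfg.equal_var)
    S_raw = maxmean(z_obs)
    null_raw = _maxmean_columns(_tstat_matrix(V, masks, cfg.equal_var))
    S_std, _ = standardize_statistic(S_raw, null_raw)
    null_std = _standardize_catalog(null_raw, null_raw)
    p = _tail_fraction(null_std, _standardize_scalar(S_raw, null_raw), cfg.smooth_pvalues)
    return S_std, p


def _standardize_scalar(x: float, catalog: np.ndarray) -> float:
    s, flagged = standardize_statistic(x, catalog)
    return x if flagged else s


def _standardize_catalog(values: np.ndarray, catalog: np.ndarray) -> np.ndarray:
    sd = catalog.std(ddof=1)
    if sd == 0.0:
        return np.asarray(values, dtype=float)
    return (np.asarray(values, dtype=float) - catalog.mean()) / sd


def _tail_fraction(null_vals: np.ndarray, observed: float, smooth: bool) -> float:
    count = int((null_vals >= observed).sum())
    B = null_vals.size
    if smooth:
        return (count + 1) / (B + 1)
    return count / B


# ---------------------------------------------------------------------------
# full enrichment
# ---------------------------------------------------------------------------

def run_enrichment(
    ds: ExpressionDataset,
    gsc: GeneSetCollection,
    kinds=None,
    cfg: EnrichmentConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every pathway under every profile kind.

    Returns ``(results, skipped)``.  ``results`` has one row per usable
    (pathway, kind): columns pathway, kind, n_genes_used, n_pairs, S,
    p_run_1..R, p, q, sorted by kind then (q, p, pathway).  q-values are
    computed per kind across pathways (the multiple-testing universe is
    the pathway collection, separately for each profile).  ``skipped``
    lists pathways excluded by the size filter with reasons.
    """
    if cfg is None:
        cfg = EnrichmentConfig()
    if kinds is None:
        kinds = list(ProfileKind)
    kinds = [ProfileKind.coerce(k) for k in kinds]

    m = len(ds.samples)
    gene_set = set(ds.genes)

    usable: list[tuple[str, list[str]]] = []
    skipped: list[dict] = []
    for name, members in gsc.items():
        genes = sorted(members & gene_set)
        if len(genes) < max(cfg.min_genes, 2):
            skipped.append(
                {"pathway": name, "reason": f"{len(genes)} gene(s) in dataset "
                 f"(min_genes = {cfg.min_genes})"}
            )
            continue
        if cfg.max_genes is not None and len(genes) > cfg.max_genes:
            skipped.append(
                {"pathway": name, "reason": f"{len(genes)} genes exceed "
                 f"max_genes = {cfg.max_genes}"}
            )
            continue
        usable.append((name, genes))
    skipped_df = pd.DataFrame(skipped, columns=["pathway", "reason"])
    if not usable:
        log.warning("no usable pathway after size filtering")
        cols = (
            ["pathway", "kind", "n_genes_used", "n_pairs", "S"]
            + [f"p_run_{r + 1}" for r in range(cfg.runs)]
            + ["p", "q"]
        )
        return pd.DataFrame(columns=cols), skipped_df

    # one shared set of label shuffles per run, reused by every pathway
    perm_runs = [
        _permutation_masks(m, ds.n_case, cfg.B, _run_seed_rng(cfg.seed, r),
                           cfg.exact_when_possible)[0]
        for r in range(cfg.runs)
    ]

    pooled_pair_scores: list[np.ndarray] = []
    records: list[dict] = []
    per_pathway: list[tuple[np.ndarray, float, list[np.ndarray]]] = []

    for name, genes in usable:
        idx = [ds.gene_index[g] for g in genes]
        X = ds.values[idx]
        for kind in kinds:
            V, _, _ = profile_matrix(X, kind)
            z_obs = two_sample_t(V, ds.case_mask, equal_var=cfg.equal_var)
            S_raw = maxmean(z_obs)
            null_by_run = [
                _maxmean_columns(_tstat_matrix(V, masks, cfg.equal_var))
                for masks in perm_runs
            ]
            per_pathway.append((z_obs, S_raw, null_by_run))
            records.append(
                {
                    "pathway": name,
                    "kind": kind.value,
                    "n_genes_used": len(genes),
                    "n_pairs": len(z_obs),
                }
            )
            pooled_pair_scores.append(z_obs)

    if cfg.standardization == "pooled_pairs":
        pooled = np.concatenate(pooled_pair_scores)
        pooled_mu, pooled_sd = pooled.mean(), pooled.std(ddof=1)

    for rec, (z_obs, S_raw, null_by_run) in zip(records, per_pathway):
        p_runs = []
        for null_raw in null_by_run:
            if cfg.standardization == "pooled_pairs" and pooled_sd > 0:
                obs = (S_raw - pooled_mu) / pooled_sd
                null_std = (null_raw - pooled_mu) / pooled_sd
            else:
                obs = _standardize_scalar(S_raw, null_raw)
                null_std = _standardize_catalog(null_raw, null_raw)
            p_runs.append(_tail_fraction(null_std, obs, cfg.smooth_pvalues))
        catalog = np.concatenate(null_by_run)
        S_std, _ = standardize_statistic(S_raw, catalog)
        for r, pr in enumerate(p_runs):
            rec[f"p_run_{r + 1}"] = pr
        rec["S"] = S_std
        rec["p"] = float(np.mean(p_runs))

    results = pd.DataFrame(records)
    results["q"] = np.nan
    for kind in kinds:
        sel = results["kind"] == kind.value
        results.loc[sel, "q"] = qvalues(results.loc[sel, "p"].to_numpy())
    results = results.sort_values(
        ["kind", "q", "p", "pathway"], kind="stable"
    ).reset_index(drop=True)
    cols = (
        ["pathway", "kind", "n_genes_used", "n_pairs", "S"]
        + [f"p_run_{r + 1}" for r in range(cfg.runs)]
        + ["p", "q"]
    )
    return results[cols], skipped_df


def significant_pathways(results: pd.DataFrame, q_threshold: float = 0.01) -> pd.DataFrame:
    """Rows called dysregulated at the q-value threshold (per kind)."""
    return results[results["q"] <= q_threshold].reset_index(drop=True)
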