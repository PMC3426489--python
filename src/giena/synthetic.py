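"""Synthetic expression data with known pair-level dysregulation.

The generator emulates the scenario the interaction-profile method is
built for: a normalized gene x sample matrix in which *pairs* of genes
change their joint behaviour between case and control samples while each
individual gene stays (statistically) unremarkable.  Baseline expression
is i.i.d. standard normal per gene and sample; selected pathways receive
injected signal pairs of one profile kind each, at a requested effect size
expressed in within-group standard deviations of the profile.

Signal construction
-------------------
Signal pairs are laid out as disjoint complete-bipartite components: a
component splits some of the pathway's genes into a left set L and a right
set R, and every L-R pair is a signal pair (components multiply up to
n_signal_pairs).  With ``preserve_marginals`` (the default) each class
keeps per-gene marginal variance exactly 1 and per-gene mean shifts far
too small for a single-gene test to flag:

* cooperation / competition ("pinned sum"): left genes take +q and right
  genes -q (cooperation) or both take +q (competition), where q is a
  shared per-sample latent carrying most of the variance and centred
  within each class so it holds no class signal.  q cancels in the
  targeted profile, which therefore sits in a narrow band of SD
  sqrt(2) tau; its centre moves by delta = effect * sqrt(2) * tau in
  cases.  delta must live in the genes' class means, and every *other*
  pair of a signal gene inherits part of it; the split across L and R is
  deliberately asymmetric (left -gamma, right the remainder) so those
  stray pairs land on the negative side of the pathway score, where they
  cannot dilute the signal.  All per-gene shifts stay at or below about
  half a within-class SD.
* redundancy ("pinned extreme"): per sample one side is high (values
  mu_c + tau eta_i, a narrow band) and the other low (values
  -mu_c +/- 2 a_c + tau eta_i, a symmetric two-branch spread), with a_c
  chosen so the per-class marginal has mean 0 and variance exactly 1.
  The pairwise maximum sits in the narrow high band; raising mu in cases
  shifts it, and mu_case is calibrated against the closed-form moments of
  the maximum of independent normals so the *realized* pooled effect
  equals the request.  Gene means and variances are identical across
  classes; only higher moments differ.
* dependency: the redundancy construction negated, which turns the pinned
  maximum into a pinned minimum shifting downwards.

Without ``preserve_marginals``, plain location shifts are used (both genes
up for cooperation/redundancy, opposite for competition, both down for
dependency), scaled so the profile moves by the requested effect.

Every injected pair, the bipartition and the realized construction
parameters are recorded in the truth manifest; the same seed always
reproduces the identical dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from math import comb, sqrt, pi

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .errors import ValidationError
from .io import (
    CASE,
    CONTROL,
    ExpressionDataset,
    GeneSetCollection,
    PhysicalInteractionNetwork,
)
from .profiles import ProfileKind

__all__ = ["SignalSpec", "SyntheticTruth", "generate", "generate_ppi"]

#: independent per-gene noise SD inside signal constructions
_TAU_SUM = 0.05
_TAU_MAX = 0.12
#: control-class location of the pinned extreme (redundancy/dependency)
_MU0 = 0.60
#: SD of max(X, Y) for X, Y i.i.d. standard normal (location-shift mode)
_SD_MAX_IID = sqrt(1.0 - 1.0 / pi)


@dataclass(frozen=True)
class SignalSpec:
    """Request to dysregulate ``n_signal_pairs`` pairs of one pathway."""

    pathway: str
    kind: ProfileKind
    n_signal_pairs: int
    effect_size: float = 2.0
    preserve_marginals: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ProfileKind.coerce(self.kind))
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if self.n_signal_pairs < 1:
            raise ValidationError("n_signal_pairs must be >= 1")


@dataclass
class SyntheticTruth:
    """Manifest of everything the generator injected."""

    seed: int
    n_genes: int
    n_case: int
    n_control: int
    pathways: dict[str, list[str]]
    signals: list[dict] = field(default_factory=list)

    def injected_pairs(self, pathway: str | None = None, kind=None) -> set[tuple[str, str]]:
        out: set[tuple[str, str]] = set()
        for s in self.signals:
            if pathway is not None and s["pathway"] != pathway:
                continue
            if kind is not None and s["kind"] != ProfileKind.coerce(kind).value:
                continue
            out.update(tuple(p) for p in s["injected_pairs"])
        return out

    def signal_pathways(self) -> dict[str, str]:
        """pathway -> profile kind of its injected signal."""
        return {s["pathway"]: s["kind"] for s in self.signals}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Substream derived from the master seed by a fixed offset key.

    Adding a new component (new key) never perturbs existing streams.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(key)))


def _component_layout(n_pairs: int, k: int) -> list[tuple[int, int]]:
    """Decompose n_pairs into complete-bipartite components K(l, r).

    Components satisfy sum(l * r) = n_pairs and sum(l + r) <= k.  Each
    component gets its own latent, so smaller components mean weaker
    correlation among the pathway's non-signal pairs; the search minimises
    the largest component (then the gene budget) by dynamic programming.
    """
    shapes = [
        (l, r) for l in range(1, n_pairs + 1) for r in range(1, l + 1)
        if l * r <= n_pairs and l + r <= k
    ]
    caps = sorted({l * r for l, r in shapes})
    for cap in caps:
        allowed = [(l, r) for l, r in shapes if l * r <= cap]
        # unbounded knapsack: fewest genes to realise exactly p pairs
        INF = k + 1
        g_min = [0] + [INF] * n_pairs
        choice: list[tuple[int, int] | None] = [None] * (n_pairs + 1)
        for p in range(1, n_pairs + 1):
            for l, r in allowed:
                e = l * r
                if e <= p and g_min[p - e] + l + r < g_min[p]:
                    g_min[p] = g_min[p - e] + l + r
                    choice[p] = (l, r)
        if g_min[n_pairs] <= k:
            layout = []
            p = n_pairs
            while p:
                l, r = choice[p]  # type: ignore[misc]
                layout.append((l, r))
                p -= l * r
            return sorted(layout, reverse=True)
    raise ValidationError(
        f"cannot lay out {n_pairs} signal pairs as disjoint complete-"
        f"bipartite components within a {k}-gene pathway (at most "
        f"K(ceil(k/2), floor(k/2)) = {(k // 2) * (k - k // 2)} pairs fit)"
    )


def _single_layout_min_right(n_pairs: int, k: int) -> list[tuple[int, int]] | None:
    """One K(l, r) with the smallest right side that fits, if any.

    Used for cooperation, where only right-side genes carry the positive
    part of the mean shift: the fewer of them, the fewer stray pairs land
    on the positive side of the pathway score.
    """
    for r in range(1, n_pairs + 1):
        if n_pairs % r == 0:
            l = n_pairs // r
            if l + r <= k:
                return [(l, r)] if l >= r else [(r, l)]
    return None


# ---------------------------------------------------------------------------
# redundancy/dependency calibration: moments of max(A, B), A _|_ B normal
# ---------------------------------------------------------------------------

def _normal_max_moments(m1: float, s1: float, m2: float, s2: float) -> tuple[float, float]:
    """Mean and variance of max(A, B) for independent normals (exact)."""
    theta = sqrt(s1 * s1 + s2 * s2)
    if theta == 0.0:
        return max(m1, m2), 0.0
    alpha = (m1 - m2) / theta
    Phi, phi = norm.cdf(alpha), norm.pdf(alpha)
    mean = m1 * Phi + m2 * (1.0 - Phi) + theta * phi
    second = (m1 * m1 + s1 * s1) * Phi + (m2 * m2 + s2 * s2) * (1.0 - Phi) \
        + (m1 + m2) * theta * phi
    return mean, second - mean * mean


def _pinned_max_moments(mu: float, tau: float) -> tuple[float, float]:
    """Moments of the pairwise max under the pinned-extreme construction.

    High side ~ N(mu, tau^2); low side is the equal mixture of
    N(-mu - 2a, tau^2) and N(-mu + 2a, tau^2) with a^2 = (1 - mu^2 - tau^2)/2.
    """
    a2 = (1.0 - mu * mu - tau * tau) / 2.0
    if a2 < -1e-12:
        raise ValidationError(f"infeasible pinned-extreme location mu={mu}")
    a = sqrt(max(a2, 0.0))
    e_lo, v_lo = _normal_max_moments(mu, tau, -mu - 2 * a, tau)
    e_hi, v_hi = _normal_max_moments(mu, tau, -mu + 2 * a, tau)
    mean = 0.5 * (e_lo + e_hi)
    second = 0.5 * (v_lo + e_lo * e_lo) + 0.5 * (v_hi + e_hi * e_hi)
    return mean, second - mean * mean


def _calibrate_mu1(effect: float, n_case: int, n_control: int,
                   mu0: float = _MU0, tau: float = _TAU_MAX) -> float:
    """mu for the case class so the realized pooled max-effect equals target."""
    e0, v0 = _pinned_max_moments(mu0, tau)

    def realized(mu1: float) -> float:
        e1, v1 = _pinned_max_moments(mu1, tau)
        sp2 = ((n_case - 1) * v1 + (n_control - 1) * v0) / (n_case + n_control - 2)
        return (e1 - e0) / sqrt(sp2)

    if effect == 0.0:
        return mu0
    hi = sqrt(1.0 - tau * tau) - 1e-9
    if realized(hi) < effect:
        raise ValidationError(
            f"effect_size {effect} exceeds the maximum "
            f"{realized(hi):.2f} attainable by the marginal-preserving "
            f"redundancy/dependency construction"
        )
    return float(brentq(lambda mu1: realized(mu1) - effect, mu0, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# per-kind injections
# ---------------------------------------------------------------------------

#: per-component deflection (expression units) applied to the signal
#: genes' class means so that non-designated ("stray") pairs move *away*
#: from the positive side of the pathway statistic instead of diluting it
_GAMMAS = (0.35, 0.15, 0.25, 0.20, 0.30, 0.10)


def _inject_pinned_sum(
    X: np.ndarray, components, case_mask: np.ndarray,
    rng: np.random.Generator, effect: float, kind: ProfileKind,
) -> dict:
    """Cooperation/competition construction (variance-preserving).

    A shared per-sample latent q carries most of each signal gene's
    variance; left genes take +q and right genes -q (cooperation) or both
    take +q (competition), so q cancels in the targeted profile, leaving
    it in a narrow band of SD sqrt(2) tau.  The band centre moves by
    delta = effect * sqrt(2) * tau in cases.  The latent is centred within
    each class, so it carries no class signal by construction.

    The profile shift must live in the genes' class means (the pair sum or
    difference of means is their combination), and every *other* pair of a
    signal gene inherits part of it.  The split is therefore deliberately
    asymmetric: left genes move by -gamma and right genes by the remainder,
    which pushes almost all stray pairs to the negative side of the
    pathway score where they cannot dilute the positive (signal) side.
    Per-gene mean shifts stay well under half a within-class SD; variances
    are preserved exactly.
    """
    tau = _TAU_SUM
    m = X.shape[1]
    delta = effect * sqrt(2.0) * tau
    case = case_mask > 0
    shifts: dict[int, float] = {}
    for c, (rows_L, rows_R) in enumerate(components):
        gamma = _GAMMAS[c % len(_GAMMAS)]
        if kind is ProfileKind.COOPERATION:
            beta_L, beta_R = -gamma, delta + gamma
        else:
            beta_L, beta_R = -gamma, -gamma - delta
        q = rng.normal(size=m)
        for grp in (case, ~case):
            q[grp] -= q[grp].mean()
        q *= sqrt(1.0 - tau * tau) / q.std()
        for rows, sign, beta in ((rows_L, 1.0, beta_L), (rows_R, -1.0, beta_R)):
            for r in rows:
                eta = rng.normal(size=m)
                if kind is ProfileKind.COOPERATION:
                    X[r] = sign * q + beta * case_mask + tau * eta
                else:  # competition: q is common-mode in the difference
                    X[r] = q + beta * case_mask + tau * eta
                shifts[r] = beta
    return {"tau": tau, "delta": delta,
            "per_gene_mean_shift": {str(r): round(b, 6) for r, b in sorted(shifts.items())}}


def _inject_pinned_extreme(
    X: np.ndarray, components, case_mask: np.ndarray,
    rng: np.random.Generator, effect: float, kind: ProfileKind,
    n_case: int, n_control: int,
) -> dict:
    """Redundancy/dependency construction with preserved marginals."""
    tau, mu0 = _TAU_MAX, _MU0
    mu1 = _calibrate_mu1(effect, n_case, n_control, mu0, tau)
    m = X.shape[1]
    mu = np.where(case_mask, mu1, mu0)
    a = np.sqrt(np.maximum((1.0 - mu**2 - tau**2) / 2.0, 0.0))
    sign = -1.0 if kind is ProfileKind.DEPENDENCY else 1.0
    for rows_L, rows_R in components:
        # which side is high per sample, balanced within each class
        high_is_L = np.zeros(m, dtype=bool)
        for cls_mask in (case_mask.astype(bool), ~case_mask.astype(bool)):
            idx = np.flatnonzero(cls_mask)
            n_hi = len(idx) // 2 + (len(idx) % 2) * int(rng.integers(2))
            high_is_L[rng.permutation(idx)[:n_hi]] = True
        for rows, is_L in ((rows_L, True), (rows_R, False)):
            for r in rows:
                eta = rng.normal(size=m)
                branch = rng.choice([-1.0, 1.0], size=m)  # per-gene branch
                high = high_is_L == is_L
                vals = np.where(high, mu + tau * eta,
                                -mu + 2 * a * branch + tau * eta)
                X[r] = sign * vals
    return {"tau": tau, "mu_control": mu0, "mu_case": mu1,
            "per_gene_mean_shift": 0.0}


def _inject_location_shift(
    X: np.ndarray, components, case_mask: np.ndarray,
    effect: float, kind: ProfileKind,
) -> dict:
    """Plain mean shifts in cases (marginals not preserved)."""
    if kind is ProfileKind.COOPERATION:
        sL = sR = effect * sqrt(2.0) / 2.0
    elif kind is ProfileKind.COMPETITION:
        sL, sR = effect * sqrt(2.0) / 2.0, -effect * sqrt(2.0) / 2.0
    elif kind is ProfileKind.REDUNDANCY:
        sL = sR = effect * _SD_MAX_IID
    else:
        sL = sR = -effect * _SD_MAX_IID
    for rows_L, rows_R in components:
        for rows, s in ((rows_L, sL), (rows_R, sR)):
            for r in rows:
                X[r] = X[r] + s * case_mask
    return {"shift_L": sL, "shift_R": sR}


# ---------------------------------------------------------------------------
# top-level generators
# ---------------------------------------------------------------------------

def generate(
    n_genes: int,
    n_case: int,
    n_control: int,
    pathways: int,
    genes_per_pathway: tuple[int, int] = (8, 12),
    signals: list[SignalSpec] | None = None,
    seed: int = 0,
) -> tuple[ExpressionDataset, GeneSetCollection, SyntheticTruth]:
    """Expression matrix + pathway collection + ground-truth manifest.

    Pathways are named ``PW001``, ``PW002``, ... and receive disjoint gene
    blocks (so a signal injected in one pathway cannot leak into another).
    Samples are ``control_01..`` then ``case_01..``.
    """
    signals = signals or []
    if min(n_genes, n_case, n_control, pathways) < 1:
        raise ValidationError("all counts must be positive")
    if n_case < 2 or n_control < 2:
        raise ValidationError("need >= 2 samples per class")
    lo, hi = genes_per_pathway
    if not (2 <= lo <= hi):
        raise ValidationError(f"bad genes_per_pathway range {genes_per_pathway}")

    m = n_case + n_control
    gene_names = [f"G{i + 1:05d}" for i in range(n_genes)]
    samples = [f"control_{j + 1:03d}" for j in range(n_control)] + [
        f"case_{j + 1:03d}" for j in range(n_case)
    ]
    labels = np.array([CONTROL] * n_control + [CASE] * n_case, dtype=object)
    case_mask = labels == CASE

    size_rng = _stream(seed, 1)
    sizes = size_rng.integers(lo, hi + 1, size=pathways)
    if sizes.sum() > n_genes:
        raise ValidationError(
            f"{pathways} pathways of {lo}-{hi} genes need up to "
            f"{int(sizes.sum())} genes but only {n_genes} exist"
        )
    pathway_map: dict[str, list[str]] = {}
    cursor = 0
    for i, k in enumerate(sizes):
        name = f"PW{i + 1:03d}"
        pathway_map[name] = gene_names[cursor: cursor + int(k)]
        cursor += int(k)

    X = _stream(seed, 0).normal(size=(n_genes, m))

    truth = SyntheticTruth(
        seed=int(seed), n_genes=n_genes, n_case=n_case, n_control=n_control,
        pathways={k: list(v) for k, v in pathway_map.items()},
    )

    claimed: set[str] = set()
    gene_row = {g: i for i, g in enumerate(gene_names)}
    for s_idx, spec in enumerate(signals):
        if spec.pathway not in pathway_map:
            raise ValidationError(f"signal pathway {spec.pathway!r} does not exist")
        members = pathway_map[spec.pathway]
        k = len(members)
        if spec.n_signal_pairs > comb(k, 2):
            raise ValidationError(
                f"{spec.n_signal_pairs} signal pairs exceed C({k},2) for {spec.pathway}"
            )
        if spec.kind is ProfileKind.COOPERATION and spec.preserve_marginals:
            layout = (_single_layout_min_right(spec.n_signal_pairs, k)
                      or _component_layout(spec.n_signal_pairs, k))
        else:
            layout = _component_layout(spec.n_signal_pairs, k)
        components = []
        genes_L_all, genes_R_all, pairs = [], [], []
        cursor_c = 0
        for l, r in layout:
            gL = members[cursor_c: cursor_c + l]
            gR = members[cursor_c + l: cursor_c + l + r]
            cursor_c += l + r
            genes_L_all += gL
            genes_R_all += gR
            pairs += [sorted((a, b)) for a in gL for b in gR]
            components.append(([gene_row[g] for g in gL],
                               [gene_row[g] for g in gR]))
        overlap = (set(genes_L_all) | set(genes_R_all)) & claimed
        if overlap:
            raise ValidationError(
                f"signal genes {sorted(overlap)[:5]} already used by another signal"
            )
        claimed |= set(genes_L_all) | set(genes_R_all)
        rng = _stream(seed, 2, s_idx)

        if not spec.preserve_marginals:
            params = _inject_location_shift(
                X, components, case_mask.astype(float), spec.effect_size, spec.kind
            )
        elif spec.kind in (ProfileKind.COOPERATION, ProfileKind.COMPETITION):
            params = _inject_pinned_sum(
                X, components, case_mask.astype(float), rng,
                spec.effect_size, spec.kind,
            )
        else:
            params = _inject_pinned_extreme(
                X, components, case_mask, rng, spec.effect_size,
                spec.kind, n_case, n_control,
            )
        params["layout"] = [list(c) for c in layout]

        truth.signals.append(
            {
                "pathway": spec.pathway,
                "kind": spec.kind.value,
                "n_signal_pairs": spec.n_signal_pairs,
                "effect_size": spec.effect_size,
                "preserve_marginals": spec.preserve_marginals,
                "left_genes": genes_L_all,
                "right_genes": genes_R_all,
                "injected_pairs": sorted(pairs),
                "construction": params,
            }
        )

    ds = ExpressionDataset(genes=gene_names, samples=samples, values=X, labels=labels)
    gsc = GeneSetCollection(
        {name: ("synthetic pathway", frozenset(genes)) for name, genes in pathway_map.items()}
    )
    return ds, gsc, truth


def generate_ppi(
    genes,
    edge_prob: float,
    planted_edges=None,
    seed: int = 0,
) -> PhysicalInteractionNetwork:
    """Erdos-Renyi interaction network plus planted edges, deduplicated."""
    if not 0.0 <= edge_prob <= 1.0:
        raise ValidationError(f"edge_prob must be in [0, 1], got {edge_prob}")
    genes = [g.upper() for g in genes]
    rng = _stream(seed, 3)
    edges: set[tuple[str, str]] = set()
    n = len(genes)
    if edge_prob > 0 and n >= 2:
        ii, jj = np.triu_indices(n, 1)
        hit = rng.random(ii.size) < edge_prob
        for a, b in zip(ii[hit], jj[hit]):
            ga, gb = genes[a], genes[b]
            edges.add((ga, gb) if ga < gb else (gb, ga))
    for a, b in planted_edges or []:
        a, b = a.upper(), b.upper()
        if a == b:
            continue
        edges.add((a, b) if a < b else (b, a))
    return PhysicalInteractionNetwork(edges)
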