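"""Paired two-choice inference, assumption checks, fold changes,
incomplete-block screening designs and mixed-model genotype means.

The paired tests operate on per-subject (arena) pairs of measurements
for the two choices. The screening design allocates a large accession
panel to blocks within complete replicate rounds; genotype means
(BLUEs) come from the mixed model

    Y = mu + REP + GEN + REP:BLOCK + E,

with REP and GEN fixed, REP:BLOCK a random intercept for blocks
nested within rounds, fitted by REML with the block-to-residual
variance ratio profiled out (1-D optimization).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "wilcoxon_signed_rank",
    "paired_t",
    "paired_test",
    "assumption_checks",
    "fold_change",
    "AlphaDesign",
    "make_alpha_design",
    "GenotypeMeansResult",
    "fit_genotype_means",
]


def _signed_rank_stat(diffs: np.ndarray):
    """(W+, doubled midranks, n) after dropping zero differences."""
    d = np.asarray(diffs, dtype=float)
    if np.isnan(d).any():
        raise ValueError("differences contain NaN")
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = sps.rankdata(np.abs(d))  # midranks on ties
    w_plus = ranks[d > 0].sum()
    ranks2 = np.rint(2 * ranks).astype(int)  # doubled ranks are integers
    return w_plus, ranks2, n


def _exact_signed_rank_p(w_plus: float, ranks2: np.ndarray) -> float:
    """Exact two-sided p by dynamic-programming enumeration.

    Counts, over all 2^n sign assignments, the distribution of the sum
    of doubled positive ranks, and returns
    ``min(1, 2 * min(P(W <= w), P(W >= w)))``.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(pairs, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired measurements.

    ``pairs`` is an (n, 2) array or a 1-D array of differences. Zero
    differences are dropped; ties are midranked. ``exact`` enumerates
    the signed-rank null for n <= 25; ``normal_approx`` uses the
    normal approximation with tie correction; ``auto`` picks exact for
    n <= 25. Returns (W+, two-sided p).
    """
    arr = np.asarray(pairs, dtype=float)
    diffs = arr[:, 0] - arr[:, 1] if arr.ndim == 2 else arr
    w_plus, ranks2, n = _signed_rank_stat(diffs)
    if mode == "auto":
        mode = "exact" if n <= 25 else "normal_approx"
    if mode == "exact":
        if n > 25:
            raise ValueError("exact mode supported for n <= 25")
        p = _exact_signed_rank_p(w_plus, ranks2)
    elif mode == "normal_approx":
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        # tie correction
        _, t = np.unique(ranks2, return_counts=True)
        var -= (t**3 - t).sum() / 48.0
        if var <= 0:
            raise ValueError("zero variance in signed-rank statistic")
        z = (w_plus - mean) / math.sqrt(var)
        p = 2 * sps.norm.sf(abs(z))
    else:
        raise ValueError("mode must be 'auto', 'exact' or 'normal_approx'")
    return float(w_plus), float(p)


def paired_t(pairs) -> tuple[float, int, float]:
    """Paired Student's t test; returns (t, df, two-sided p)."""
    arr = np.asarray(pairs, dtype=float)
    diffs = arr[:, 0] - arr[:, 1] if arr.ndim == 2 else arr
    n = len(diffs)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    sd = diffs.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences")
    t = diffs.mean() / (sd / math.sqrt(n))
    df = n - 1
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def assumption_checks(sample_groups: list) -> dict:
    """Shapiro normality p per group plus a Levene homogeneity p."""
    for g in sample_groups:
        if len(g) < 3:
            raise ValueError("each group needs at least 3 observations")
    shapiro_p = [float(sps.shapiro(np.asarray(g, float)).pvalue) for g in sample_groups]
    out = {"shapiro_p": shapiro_p}
    if len(sample_groups) >= 2:
        out["levene_p"] = float(sps.levene(*map(np.asarray, sample_groups)).pvalue)
    return out


def paired_test(pairs, mode: str = "auto", alpha: float = 0.05) -> dict:
    """Paired comparison with assumption-based routing.

    ``auto`` runs a Shapiro test on the differences and uses the
    paired t test when normality is not rejected at ``alpha``, the
    Wilcoxon signed-rank test otherwise. Returns a dict with the test
    used, statistic and p-value.
    """
    arr = np.asarray(pairs, dtype=float)
    diffs = arr[:, 0] - arr[:, 1] if arr.ndim == 2 else arr
    if mode == "auto":
        normal = sps.shapiro(diffs).pvalue >= alpha
        mode = "paired_t" if normal else "wilcoxon"
    if mode == "paired_t":
        t, df, p = paired_t(diffs)
        return {"test": "paired_t", "statistic": t, "df": df, "p": p}
    if mode == "wilcoxon":
        w, p = wilcoxon_signed_rank(diffs)
        return {"test": "wilcoxon", "statistic": w, "p": p}
    raise ValueError("mode must be 'auto', 'paired_t' or 'wilcoxon'")


def fold_change(mean_a: float, mean_b: float) -> tuple[float, int]:
    """Larger-over-smaller ratio of two group means: (raw, rounded)."""
    lo, hi = sorted([mean_a, mean_b])
    if lo <= 0:
        raise ValueError("fold change needs positive means")
    raw = hi / lo
    return raw, int(round(raw))


@dataclass(frozen=True)
class AlphaDesign:
    """Round/block allocation of accessions for a multi-round screen."""

    n_accessions: int
    n_rounds: int
    blocks_per_round: int
    block_size: int
    allocation: pd.DataFrame  # accession, round, block, position, plate_row, reference_side

    def validate(self) -> None:
        a = self.allocation
        for r, grp in a.groupby("round"):
            if sorted(grp["accession"]) != list(range(self.n_accessions)):
                raise ValueError(f"round {r} does not contain every accession exactly once")
            sizes = grp.groupby("block").size()
            if not (sizes == self.block_size).all():
                raise ValueError(f"round {r} has blocks of the wrong size")


def make_alpha_design(
    n_accessions: int,
    n_rounds: int,
    blocks_per_round: int,
    block_size: int,
    seed: int = 0,
    positions_per_plate_row: int = 5,
) -> AlphaDesign:
    """Seeded randomized incomplete-block allocation.

    Every round is an independent random partition of all accessions
    into ``blocks_per_round`` blocks of ``block_size`` (each accession
    appears exactly once per round). Within a block, arenas are filled
    row by row and the reference leaf-disc side alternates by plate
    row (left on even rows) to cancel position bias.
    """
    if n_accessions != blocks_per_round * block_size:
        raise ValueError("n_accessions must equal blocks_per_round * block_size")
    rng = np.random.default_rng(seed)
    rows = []
    for rnd in range(n_rounds):
        perm = rng.permutation(n_accessions)
        for b in range(blocks_per_round):
            members = perm[b * block_size : (b + 1) * block_size]
            for pos, acc in enumerate(members):
                plate_row = pos // positions_per_plate_row
                rows.append(
                    {
                        "accession": int(acc),
                        "round": rnd,
                        "block": b,
                        "position": pos,
                        "plate_row": plate_row,
                        "reference_side": "left" if plate_row % 2 == 0 else "right",
                    }
                )
    design = AlphaDesign(
        n_accessions, n_rounds, blocks_per_round, block_size, pd.DataFrame(rows)
    )
    design.validate()
    return design


@dataclass
class GenotypeMeansResult:
    means: pd.DataFrame  # genotype, blue, se
    sigma2_block: float
    sigma2_e: float
    mu: float
    reml_loglik: float


def _design_matrices(obs: pd.DataFrame):
    """X (intercept + round + genotype treatment dummies), group codes."""
    y = obs["value"].to_numpy(dtype=float)
    rounds = pd.Categorical(obs["round"])
    genos = pd.Categorical(obs["genotype"])
    n = len(obs)
    n_r, n_g = len(rounds.categories), len(genos.categories)
    X = np.zeros((n, 1 + (n_r - 1) + (n_g - 1)))
    X[:, 0] = 1.0
    rc = rounds.codes
    gc = genos.codes
    for j in range(1, n_r):
        X[rc == j, j] = 1.0
    for j in range(1, n_g):
        X[gc == j, n_r - 1 + j] = 1.0
    groups = pd.Categorical(
        obs["round"].astype(str) + ":" + obs["block"].astype(str)
    ).codes
    return y, X, groups, rounds.categories, genos.categories, n_r, n_g


def fit_genotype_means(observations: pd.DataFrame) -> GenotypeMeansResult:
    """REML fit of Y = mu + REP + GEN + REP:BLOCK + E; genotype BLUEs.

    ``observations`` needs columns genotype, round, block, value. The
    single variance ratio lambda = sigma2_block / sigma2_e is profiled
    and optimized on a log grid with Brent refinement; fixed effects
    follow by GLS. Genotype means are estimated marginal means
    (averaged over rounds) with standard errors from the GLS
    covariance. With a balanced design and lambda -> 0 they reduce to
    ordinary genotype means.
    """
    obs = observations.reset_index(drop=True)
    for col in ("genotype", "round", "block", "value"):
        if col not in obs.columns:
            raise ValueError(f"observations missing column {col!r}")
    y, X, groups, _, geno_cats, n_r, n_g = _design_matrices(obs)
    n, p = X.shape
    if n <= p:
        raise ValueError("design not identifiable: fewer observations than parameters")

    G = groups.max() + 1
    ng = np.bincount(groups, minlength=G).astype(float)
    # group aggregates for the Woodbury form of V^-1
    SX = np.zeros((G, p))
    np.add.at(SX, groups, X)
    Sy = np.bincount(groups, weights=y, minlength=G)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def gls(lam: float):
        c = lam / (1.0 + ng * lam)  # per-group shrinkage weight
        XtWX = XtX - (SX * c[:, None]).T @ SX
        XtWy = Xty - SX.T @ (c * Sy)
        beta = np.linalg.solve(XtWX, XtWy)
        # residual quadratic form y'Wy - 2 b'X'Wy + b'X'WX b
        ytWy = yty - float(c @ (Sy**2))
        rss = ytWy - 2 * float(beta @ XtWy) + float(beta @ XtWX @ beta)
        return beta, XtWX, rss

    def neg_reml(log_lam: float) -> float:
        lam = math.exp(log_lam)
        beta, XtWX, rss = gls(lam)
        if rss <= 0:
            return np.inf
        s2 = rss / (n - p)
        sign, logdet_XtWX = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        logdet_V = float(np.log1p(ng * lam).sum())
        return 0.5 * ((n - p) * math.log(s2) + logdet_V + logdet_XtWX + (n - p))

    grid = np.linspace(-12, 6, 37)
    vals = [neg_reml(g) for g in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_reml, bounds=(lo, hi), method="bounded")
    lam = math.exp(res.x)
    # compare against the boundary lambda -> 0 (no block variance)
    if neg_reml(-30.0) <= res.fun:
        lam = 0.0

    beta, XtWX, rss = gls(lam)
    s2e = rss / (n - p)
    s2b = lam * s2e
    cov = np.linalg.inv(XtWX) * s2e

    # estimated marginal mean per genotype: mu + mean(round effects) + gen_j
    rows = []
    base = np.zeros(p)
    base[0] = 1.0
    base[1:n_r] = 1.0 / n_r  # average over rounds (baseline round contributes 0)
    for j, gname in enumerate(geno_cats):
        cvec = base.copy()
        if j > 0:
            cvec[n_r - 1 + j] = 1.0
        est = float(cvec @ beta)
        se = float(math.sqrt(cvec @ cov @ cvec))
        rows.append({"genotype": gname, "blue": est, "se": se})
    return GenotypeMeansResult(
        means=pd.DataFrame(rows),
        sigma2_block=float(s2b),
        sigma2_e=float(s2e),
        mu=float(beta[0]),
        reml_loglik=float(-res.fun),
    )
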