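"""Replicate-based evaluation: type-1 error, power, and Q-Q summaries.

The study design holds genotypes (and covariates) fixed and redraws
phenotypes per replicate, as when a consortium distributes simulated
phenotype replicates over real genotypes.  Single-variant tests across
all variants of a panel are computed by a batched IRLS engine
(logistic fits vectorized over variants); its p-values match the
per-variant public functions and a dedicated test asserts that.

Type-1 error is pooled across variants sharing the same carrier count
(M-tilde-AC: individuals with dosage > 0), the resolution at which test
calibration varies; half-widths are 2*sqrt(alpha(1-alpha)/N) simulation
error bars.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .collapse import CollapsingConfig, classify_maf, test_region_by_class
from .containers import (
    GenotypeMatrix,
    SubregionPartition,
    compute_mac_tilde,
    compute_maf,
    filter_polymorphic,
)
from .firth import fit_mle
from .score import saddlepoint_pvalues
from .simulate import (
    SimulationSpec,
    gen_alt_phenotypes,
    gen_genotypes,
    gen_null_phenotypes,
    spec_partition,
)

__all__ = [
    "ReplicateResults",
    "PooledRate",
    "run_replicates",
    "pool_type1_by_mac",
    "power_by_target",
    "qq_points",
    "bonferroni_adjust",
    "SINGLE_VARIANT_METHODS",
    "REGION_METHODS",
]

SINGLE_VARIANT_METHODS = ("lrt", "plrt", "score", "score-var", "score-var-kurt")
REGION_METHODS = ("burden", "skat", "skato")
DEFAULT_ALPHAS = (0.01, 0.05, 1e-6, 5e-8)

_ETA_CLIP = 30.0
_IRLS_ITER = 30
_IRLS_TOL = 1e-7


# ---------------------------------------------------------------- batched fits


def _batched_logistic(y, Xc, G, firth: bool, constrained: bool, beta_init=None):
    """IRLS for m logistic models sharing covariates, one genotype column each.

    Designs are [Xc, g_j].  ``constrained`` fixes the genotype
    coefficient at 0 while (for Firth) the penalty keeps the full
    design's information.  Returns (beta (m,4), loglik, penalized_loglik,
    converged) arrays.
    """
    n, m = G.shape
    p = Xc.shape[1]
    beta = np.zeros((m, p + 1)) if beta_init is None else beta_init.copy()
    if constrained:
        beta[:, p] = 0.0
    active = np.ones(m, dtype=bool)
    for _ in range(_IRLS_ITER):
        # iterate only on unconverged columns: per-column quantities are
        # independent reductions, so values match the full-batch ones
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        Ga = np.ascontiguousarray(G[:, idx])
        ba = beta[idx]
        eta = Xc @ ba[:, :p].T + Ga * ba[:, p]
        pi = expit(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        w = np.maximum(pi * (1.0 - pi), 1e-12)
        Acc = np.einsum("ip,im,iq->mpq", Xc, w, Xc, optimize=True)
        Acg = np.einsum("ip,im,im->mp", Xc, w, Ga, optimize=True)
        Agg = np.einsum("im,im,im->m", w, Ga, Ga, optimize=True)
        A = np.empty((idx.size, p + 1, p + 1))
        A[:, :p, :p] = Acc
        A[:, :p, p] = Acg
        A[:, p, :p] = Acg
        A[:, p, p] = Agg
        if firth:
            Ainv = np.linalg.inv(A)
            t1 = np.einsum("ip,mpq,iq->im", Xc, Ainv[:, :p, :p], Xc, optimize=True)
            t2 = 2.0 * (Xc @ Ainv[:, :p, p].T) * Ga
            t3 = (Ga**2) * Ainv[:, p, p][None, :]
            h = w * (t1 + t2 + t3)
            resid = y[:, None] - pi + h * (0.5 - pi)
        else:
            resid = y[:, None] - pi
        score_c = Xc.T @ resid  # p x m_active
        score_g = np.einsum("im,im->m", Ga, resid)
        if constrained:
            rhs = score_c.T[:, :, None]
            step = np.linalg.solve(Acc, rhs)[:, :, 0]
            max_score = np.abs(score_c).max(axis=0)
        else:
            full_score = np.concatenate([score_c.T, score_g[:, None]], axis=1)
            step = np.linalg.solve(A, full_score[:, :, None])[:, :, 0]
            max_score = np.abs(full_score).max(axis=1)
        still = max_score >= _IRLS_TOL
        active[idx[~still]] = False
        if not np.any(still):
            break
        norm = np.abs(step).max(axis=1)
        scale = np.where(norm > 5.0, 5.0 / np.maximum(norm, 1e-300), 1.0)
        step = step * (scale * still)[:, None]
        if constrained:
            beta[idx, :p] += step
        else:
            beta[idx] += step
    eta = Xc @ beta[:, :p].T + G * beta[:, p]
    pi = expit(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    ll = np.sum(y[:, None] * eta - np.logaddexp(0.0, eta), axis=0)
    w = np.maximum(pi * (1.0 - pi), 1e-12)
    Acc = np.einsum("ip,im,iq->mpq", Xc, w, Xc, optimize=True)
    Acg = np.einsum("ip,im,im->mp", Xc, w, G, optimize=True)
    Agg = np.einsum("im,im,im->m", w, G, G, optimize=True)
    A = np.empty((m, p + 1, p + 1))
    A[:, :p, :p] = Acc
    A[:, :p, p] = Acg
    A[:, p, :p] = Acg
    A[:, p, p] = Agg
    sign, logdet = np.linalg.slogdet(A)
    lp = ll + 0.5 * np.where(sign > 0, logdet, -np.inf)
    converged = ~active
    return beta, ll, lp, converged


def _single_variant_engine(y, Xc, G, methods, B, rng):
    """All requested single-variant tests for one phenotype replicate.

    Returns dict method -> (p-values (m,), converged flags (m,)).
    """
    n, m = G.shape
    out = {}
    null_fit = fit_mle(y, Xc)
    pi0 = null_fit.fitted_probs
    s = pi0 * (1.0 - pi0)
    need_score = any(meth.startswith("score") for meth in methods)
    if need_score:
        XtW = Xc.T * s
        coef = np.linalg.solve(XtW @ Xc, XtW @ G)
        Gt = G - Xc @ coef
        U = Gt.T @ (y - pi0)
        V = np.einsum("im,im->m", Gt, s[:, None] * Gt)
        V = np.maximum(V, 1e-300)
        ok = V > 1e-12
        if "score" in methods:
            statv = U**2 / V
            out["score"] = (stats.chi2.sf(statv, 1), ok)
        if "score-var" in methods or "score-var-kurt" in methods:
            mu_Q = V
            corr = np.einsum("im,i->m", Gt**4, s) - 6.0 * np.einsum("im,i->m", Gt**4, s**2)
            sigma_Q = np.sqrt(np.maximum(2.0 * V**2 + corr, 1e-300))
            Q = U**2
            if "score-var" in methods:
                t = (Q - mu_Q) / sigma_Q * np.sqrt(2.0) + 1.0
                out["score-var"] = (stats.chi2.sf(np.maximum(t, 0.0), 1), ok)
            if "score-var-kurt" in methods:
                # p from the exact-CGF saddlepoint (bulk- and
                # tail-accurate, no moment-map support artifact)
                out["score-var-kurt"] = (saddlepoint_pvalues(U, Gt, pi0), ok)
    if "lrt" in methods:
        init = np.zeros((m, Xc.shape[1] + 1))
        init[:, : Xc.shape[1]] = null_fit.coefficients
        _, ll_full, _, conv = _batched_logistic(y, Xc, G, firth=False, constrained=False, beta_init=init)
        stat = np.maximum(2.0 * (ll_full - null_fit.loglik), 0.0)
        out["lrt"] = (stats.chi2.sf(stat, 1), conv)
    if "plrt" in methods:
        _, _, lp_full, conv_f = _batched_logistic(y, Xc, G, firth=True, constrained=False)
        _, _, lp_null, conv_n = _batched_logistic(y, Xc, G, firth=True, constrained=True)
        stat = np.maximum(2.0 * (lp_full - lp_null), 0.0)
        out["plrt"] = (stats.chi2.sf(stat, 1), conv_f & conv_n)
    return out


# ---------------------------------------------------------------- results


@dataclass
class PooledRate:
    """Empirical rejection rate pooled over a group of tests."""

    group_key: object
    alpha: float
    rate: float
    N: int
    half_width: float
    method: str = ""


@dataclass
class ReplicateResults:
    """P-values from R phenotype replicates over fixed genotypes."""

    scenario: str
    R: int
    base_seed: int
    variant_table: pd.DataFrame
    single: dict = field(default_factory=dict)  # method -> (R, m) p-values
    single_status: dict = field(default_factory=dict)
    region: Optional[pd.DataFrame] = None
    partition: Optional[SubregionPartition] = None

    def replicate_seed(self, r: int) -> int:
        return (self.base_seed + r) % 2**31

    def to_frame(self) -> pd.DataFrame:
        frames = []
        ids = self.variant_table["id"].to_numpy()
        for method, P in self.single.items():
            R, m = P.shape
            frames.append(
                pd.DataFrame(
                    {
                        "replicate": np.repeat(np.arange(R), m),
                        "target": np.tile(ids, R),
                        "method": method,
                        "p": P.ravel(),
                    }
                )
            )
        if self.region is not None:
            frames.append(self.region.rename(columns={"subregion": "target"}))
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def run_replicates(
    spec: SimulationSpec,
    methods: Sequence[str],
    R: int,
    scenario: str = "null",
    base_seed: int = 1,
    classes: Sequence[str] = ("rare", "rare_lf", "all"),
    B: int = 1000,
    progress: bool = False,
) -> ReplicateResults:
    """Generate genotypes once, redraw phenotypes R times, run the tests.

    Replicate r uses phenotype seed (base_seed + r) mod 2^31, so any
    replicate can be regenerated in isolation.  Tests run on the
    complete-case subsample; ``B`` is the bootstrap size per replicate
    for kurtosis-adjusted tests.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    single_methods = [m for m in methods if m in SINGLE_VARIANT_METHODS]
    region_methods = [m for m in methods if m in REGION_METHODS]
    unknown = set(methods) - set(single_methods) - set(region_methods)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")

    gm_full = gen_genotypes(spec, seed=spec.seed)
    subregion_full = np.array([v.subregion for v in spec.variants])
    gm_poly = filter_polymorphic(gm_full)
    poly_ids = {v.id for v in gm_poly.variants}
    keep = np.array([v.id in poly_ids for v in gm_full.variants])
    subregions = subregion_full[keep]

    mask = gen_null_phenotypes(spec, gm_full, base_seed).complete_case_mask()
    G = gm_poly.dosages[mask]
    n = G.shape[0]
    # drop variants monomorphic within the analyzed subsample
    poly_cc = np.array(
        [np.unique(G[:, j]).size >= 2 for j in range(G.shape[1])]
    )
    G = G[:, poly_cc]
    subregions = subregions[poly_cc]
    kept_variants = [v for v, k in zip(gm_poly.variants, poly_cc) if k]
    m = G.shape[1]
    mac = np.array([compute_mac_tilde(G[:, j]) for j in range(m)])
    maf = np.array([compute_maf(G[:, j]) for j in range(m)])
    variant_table = pd.DataFrame(
        {
            "id": [v.id for v in kept_variants],
            "subregion": subregions,
            "mac_tilde": mac,
            "maf": maf,
            "class": classify_maf(maf),
            "functional": [v.functional for v in kept_variants],
        }
    )
    partition = SubregionPartition(subregions, int(subregion_full.max()))

    ids = variant_table["id"].to_numpy()
    gm_cc = GenotypeMatrix(
        G, [s for s, k in zip(gm_poly.sample_ids, mask) if k], kept_variants
    ).annotate()

    single_p = {meth: np.ones((R, m)) for meth in single_methods}
    single_ok = {meth: np.ones((R, m), dtype=bool) for meth in single_methods}
    region_rows = []
    gen_phen = gen_null_phenotypes if scenario == "null" else gen_alt_phenotypes

    for r in range(R):
        rseed = (base_seed + r) % 2**31
        phen = gen_phen(spec, gm_full, rseed)
        y = phen.outcome[mask]
        Xc = phen.covariate_design(mask)
        rng = np.random.default_rng((rseed * 2 + 1) % 2**31)
        if single_methods:
            res = _single_variant_engine(y, Xc, G, single_methods, B, rng)
            for meth, (p, ok) in res.items():
                single_p[meth][r] = p
                single_ok[meth][r] = ok
        if region_methods:
            cfg = CollapsingConfig(B=B, seed=int((rseed * 2 + 2) % 2**31))
            null_fit = fit_mle(y, Xc)
            results = test_region_by_class(
                y, Xc, gm_cc, partition, list(classes), region_methods, cfg, null_fit
            )
            for tr in results:
                region_rows.append(
                    {
                        "replicate": r,
                        "target": tr.target,
                        "class": tr.df_or_params.get("class"),
                        "method": tr.method,
                        "p": tr.p_value,
                        "status": tr.status.value,
                    }
                )
        if progress and (r + 1) % 100 == 0:
            print(f"  replicate {r + 1}/{R}", flush=True)

    region_df = pd.DataFrame(region_rows) if region_rows else None
    return ReplicateResults(
        scenario=scenario,
        R=R,
        base_seed=base_seed,
        variant_table=variant_table,
        single=single_p,
        single_status=single_ok,
        region=region_df,
        partition=partition,
    )


# ---------------------------------------------------------------- summaries


def pool_type1_by_mac(
    rr: ReplicateResults,
    variants: Optional[pd.DataFrame] = None,
    alpha: float = 0.01,
    mac_groups: Optional[Sequence[tuple[int, int]]] = None,
) -> list[PooledRate]:
    """Proportion of null p-values below alpha, pooled by carrier count.

    Variants with the same M-tilde-AC (on the analyzed subsample) form
    one group; ``mac_groups`` optionally pools ranges [lo, hi] instead.
    N = R * (group size); half_width = 2*sqrt(alpha(1-alpha)/N).
    """
    if rr.scenario != "null":
        raise ValueError("type-1 pooling requires null-scenario results")
    vt = rr.variant_table if variants is None else variants
    mac = vt["mac_tilde"].to_numpy()
    if mac_groups is None:
        groups = [(int(v), int(v)) for v in np.unique(mac)]
    else:
        groups = [(int(lo), int(hi)) for lo, hi in mac_groups]
    out = []
    for method, P in rr.single.items():
        for lo, hi in groups:
            cols = np.flatnonzero((mac >= lo) & (mac <= hi))
            if cols.size == 0:
                continue
            pv = P[:, cols].ravel()
            N = pv.size
            rate = float(np.mean(pv < alpha))
            hw = 2.0 * float(np.sqrt(alpha * (1 - alpha) / N))
            key = lo if lo == hi else (lo, hi)
            out.append(PooledRate(key, alpha, rate, N, hw, method))
    return out


def power_by_target(
    rr: ReplicateResults, alphas: Sequence[float] = DEFAULT_ALPHAS
) -> pd.DataFrame:
    """Rejection rate per target at each significance level.

    Single-variant rows are per variant; region rows per
    (subregion, class, method).
    """
    rows = []
    ids = rr.variant_table["id"].to_numpy()
    for method, P in rr.single.items():
        for j, vid in enumerate(ids):
            row = {"target": vid, "class": rr.variant_table["class"].iloc[j], "method": method}
            for a in alphas:
                row[f"power@{a:g}"] = float(np.mean(P[:, j] < a))
            rows.append(row)
    if rr.region is not None:
        for (target, vclass, method), grp in rr.region.groupby(["target", "class", "method"]):
            row = {"target": target, "class": vclass, "method": method}
            for a in alphas:
                row[f"power@{a:g}"] = float(np.mean(grp["p"].to_numpy() < a))
            rows.append(row)
    return pd.DataFrame(rows)


def qq_points(pvals: np.ndarray) -> np.ndarray:
    """(expected, observed) -log10 p pairs for a Q-Q plot.

    Expected quantiles are (i - 0.5)/n; zero p-values are clamped to
    1/(10 n) with a warning.
    """
    import warnings

    pv = np.asarray(pvals, dtype=float)
    if pv.size == 0:
        raise ValueError("empty p-value vector")
    n = pv.size
    if np.any(pv == 0):
        warnings.warn(f"{int(np.sum(pv == 0))} zero p-values clamped to {1 / (10 * n):g}")
        pv = np.maximum(pv, 1.0 / (10.0 * n))
    obs = np.sort(pv)
    exp = (np.arange(1, n + 1) - 0.5) / n
    return np.column_stack([-np.log10(exp), -np.log10(obs)])


def bonferroni_adjust(pvals: np.ndarray) -> np.ndarray:
    """Bonferroni correction min(1, m*p) within the declared family."""
    pv = np.asarray(pvals, dtype=float)
    return np.minimum(1.0, pv * pv.size)
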