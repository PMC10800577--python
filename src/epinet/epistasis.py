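"""Two-stage SNP-pair interaction scan.

Stage 1 screens every eligible SNP pair with a fast log-linear statistic: the
observed 3 x 3 x 2 genotype-phenotype table is compared against the Kirkwood
superposition approximation (KSA) of the homogeneous-association log-linear
model,

    p_KSA(i, j, k)  proportional to  p(i,j) p(i,k) p(j,k) / (p(i) p(j) p(k)),

normalised over the 18 cells, and the statistic tau = 2 (LL_saturated -
LL_KSA) is referred to a chi-square distribution with 4 degrees of freedom
(the (3-1) x (3-1) interaction df). Because the KSA log-likelihood can never
exceed the maximised homogeneous-association log-likelihood, tau upper-bounds
the exact 4-df interaction likelihood ratio: the screen never under-screens.

Stage 2 fits, on pairs passing the screen, the logistic interaction model

    logit P(case) = b0 + b1 gA + b2 gB + b3 gA gB

on complete cases with dosage coding 0/1/2, by iteratively reweighted least
squares, and reports the Wald p-value for b3 and the interaction odds ratio
OR = exp(b3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.stats import chi2, norm

from .io import MISSING, PHENO_CASE, PHENO_CONTROL, GenotypeDataset

STATUS_OK = "ok"
STATUS_SCREEN_ONLY = "screen_only"
STATUS_NON_CONVERGED = "non_converged"
STATUS_DEGENERATE = "degenerate"

_SEPARATION_BETA = 15.0
_IRLS_TOL = 1e-8
_IRLS_MAX_ITER = 50
_MIN_COMPLETE_CASES = 10


@dataclass
class PairTable:
    """3 x 3 x 2 genotype-phenotype contingency table for one SNP pair.

    ``counts[i, j, k]``: genotype i at SNP A, j at SNP B, phenotype k
    (0 = control, 1 = case), over samples with both genotypes and the
    phenotype non-missing.
    """

    counts: np.ndarray
    n_used: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3, 2):
            raise ValueError("pair table must be 3 x 3 x 2")
        if int(self.counts.sum()) != self.n_used:
            raise ValueError("pair table counts do not sum to n_used")


@dataclass
class SnpPairResult:
    snp_a: str
    snp_b: str
    tau: float
    p_screen: float
    beta3: float | None
    se: float | None
    p_wald: float | None
    or_value: float | None
    n_used: int
    status: str


def pair_table(
    dosages_a: np.ndarray, dosages_b: np.ndarray, phenotypes: np.ndarray
) -> PairTable:
    """Complete-case 3 x 3 x 2 table; invariant to sample order."""
    ga = np.asarray(dosages_a)
    gb = np.asarray(dosages_b)
    ph = np.asarray(phenotypes)
    if not (len(ga) == len(gb) == len(ph)):
        raise ValueError("dosage and phenotype vectors must have equal length")
    ok = (ga != MISSING) & (gb != MISSING) & ((ph == PHENO_CASE) | (ph == PHENO_CONTROL))
    ga, gb, ph = ga[ok], gb[ok], ph[ok]
    idx = ga.astype(np.int64) * 6 + gb.astype(np.int64) * 2 + (ph == PHENO_CASE)
    counts = np.bincount(idx, minlength=18).reshape(3, 3, 2)
    return PairTable(counts=counts, n_used=int(ok.sum()))


def kirkwood_fit(table: PairTable) -> np.ndarray:
    """Kirkwood superposition approximation of the 3-way cell probabilities.

    Cells whose required pairwise or single marginals are zero get probability
    zero; the remainder are renormalised to sum to one.
    """
    if table.n_used < 1:
        raise ValueError("empty table")
    p = table.counts / table.n_used
    p_ij = p.sum(axis=2)
    p_ik = p.sum(axis=1)
    p_jk = p.sum(axis=0)
    p_i = p.sum(axis=(1, 2))
    p_j = p.sum(axis=(0, 2))
    p_k = p.sum(axis=(0, 1))

    num = p_ij[:, :, None] * p_ik[:, None, :] * p_jk[None, :, :]
    den = p_i[:, None, None] * p_j[None, :, None] * p_k[None, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        fitted = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    total = fitted.sum()
    if total <= 0:
        raise ValueError("KSA fit degenerate: all cells have zero marginal support")
    return fitted / total


def boost_screen(table: PairTable) -> tuple[float, float]:
    """Screening statistic tau and its chi-square(4) upper-tail p-value.

    tau = 2 (LL_saturated - LL_KSA) with 0 log 0 = 0 in the saturated term.
    Raises ``ValueError`` when a cell with a nonzero count has zero fitted
    KSA probability (tau undefined; callers mark the pair degenerate).
    """
    n = table.counts
    fitted = kirkwood_fit(table)
    obs = n / table.n_used
    nz = n > 0
    if np.any(nz & (fitted <= 0)):
        raise ValueError("tau undefined: observed count in a zero-KSA cell")
    ll_sat = float((n[nz] * np.log(obs[nz])).sum())
    ll_ksa = float((n[nz] * np.log(fitted[nz])).sum())
    tau = 2.0 * (ll_sat - ll_ksa)
    tau = max(tau, 0.0)  # clip numerical negatives (tau >= 0 analytically)
    return tau, float(chi2.sf(tau, df=4))


def _irls_logistic(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """IRLS fit of a logistic regression; returns (beta, cov, converged).

    Convergence: relative log-likelihood change < 1e-8 within 50 iterations.
    """
    n, k = X.shape
    beta = np.zeros(k)
    ll_old = -np.inf
    converged = False
    for _ in range(_IRLS_MAX_ITER):
        eta = X @ beta
        eta = np.clip(eta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        z = eta + (y - mu) / w
        XtW = X.T * w
        try:
            beta = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            return beta, np.full((k, k), np.nan), False
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        if abs(ll - ll_old) < _IRLS_TOL * (abs(ll_old) + _IRLS_TOL):
            converged = True
            break
        ll_old = ll
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    try:
        cov = np.linalg.inv((X.T * w) @ X)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
    return beta, cov, converged


def logistic_interaction_test(
    dosages_a: np.ndarray, dosages_b: np.ndarray, phenotypes: np.ndarray
) -> dict:
    """Interaction coefficient, SE, Wald p and OR for one SNP pair.

    Returns a dict with keys beta3, se, p_wald, or_value, n_used, status.
    Status ``degenerate`` marks rank-deficient designs (e.g. a monomorphic
    SNP), ``non_converged`` marks IRLS failure or quasi-separation
    (|beta3| > 15).
    """
    ga = np.asarray(dosages_a, dtype=float)
    gb = np.asarray(dosages_b, dtype=float)
    ph = np.asarray(phenotypes)
    ok = (ga != MISSING) & (gb != MISSING) & ((ph == PHENO_CASE) | (ph == PHENO_CONTROL))
    ga, gb = ga[ok], gb[ok]
    y = (ph[ok] == PHENO_CASE).astype(float)
    n = len(y)
    none_result = dict(beta3=None, se=None, p_wald=None, or_value=None, n_used=n)
    if n < _MIN_COMPLETE_CASES or y.min() == y.max():
        return dict(**none_result, status=STATUS_DEGENERATE)

    X = np.column_stack([np.ones(n), ga, gb, ga * gb])
    if np.linalg.matrix_rank(X) < 4:
        return dict(**none_result, status=STATUS_DEGENERATE)

    beta, cov, converged = _irls_logistic(X, y)
    beta3 = float(beta[3])
    var3 = float(cov[3, 3]) if np.all(np.isfinite(cov)) else np.nan
    if not converged or not np.isfinite(var3) or var3 <= 0 or abs(beta3) > _SEPARATION_BETA:
        return dict(**none_result, status=STATUS_NON_CONVERGED)
    se = float(np.sqrt(var3))
    p_wald = float(2.0 * norm.sf(abs(beta3) / se))
    return dict(
        beta3=beta3, se=se, p_wald=p_wald, or_value=float(np.exp(beta3)),
        n_used=n, status=STATUS_OK,
    )


def _canonical_keys(dataset: GenotypeDataset) -> dict[str, tuple]:
    """Sort key per variant id: ascending by (chromosome, position, id)."""
    return {v.variant_id: (v.chrom, v.pos, v.variant_id) for v in dataset.variants}


def _screen_block(
    onehot_pheno: np.ndarray, onehot: np.ndarray, ai: np.ndarray, bi: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised KSA screen for a block of SNP pairs.

    ``onehot_pheno[i, k]`` is the (n_samples x n_variants) indicator of
    genotype i and phenotype k; ``onehot[j]`` of genotype j. Returns
    ``(tau, n_used, counts, degenerate)`` with counts shaped (P, 3, 3, 2).
    Counting is plain vectorised arithmetic: cell (i, j, k) of each pair is
    the inner product of the two indicator columns.
    """
    P = len(ai)
    counts = np.empty((P, 3, 3, 2), dtype=np.float64)
    for i in range(3):
        for k in range(2):
            left = onehot_pheno[i, k][:, ai]
            for j in range(3):
                counts[:, i, j, k] = np.einsum(
                    "sp,sp->p", left, onehot[j][:, bi], optimize=True
                )
    n_used = counts.sum(axis=(1, 2, 3))
    safe_n = np.where(n_used > 0, n_used, 1.0)
    p = counts / safe_n[:, None, None, None]
    p_ij = p.sum(axis=3)
    p_ik = p.sum(axis=2)
    p_jk = p.sum(axis=1)
    p_i = p.sum(axis=(2, 3))
    p_j = p.sum(axis=(1, 3))
    p_k = p.sum(axis=(1, 2))
    num = p_ij[:, :, :, None] * p_ik[:, :, None, :] * p_jk[:, None, :, :]
    den = p_i[:, :, None, None] * p_j[:, None, :, None] * p_k[:, None, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        fitted = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    totals = fitted.sum(axis=(1, 2, 3))
    ok_total = totals > 0
    fitted /= np.where(ok_total, totals, 1.0)[:, None, None, None]

    nz = counts > 0
    degenerate = (~ok_total) | (n_used < 1) | np.any(nz & (fitted <= 0), axis=(1, 2, 3))
    with np.errstate(divide="ignore", invalid="ignore"):
        log_obs = np.where(nz, np.log(np.where(nz, p, 1.0)), 0.0)
        log_fit = np.where(nz & (fitted > 0), np.log(np.where(fitted > 0, fitted, 1.0)), 0.0)
    ll_sat = (counts * log_obs).sum(axis=(1, 2, 3))
    ll_ksa = (counts * log_fit).sum(axis=(1, 2, 3))
    tau = np.clip(2.0 * (ll_sat - ll_ksa), 0.0, None)
    return tau, n_used.astype(np.int64), counts.astype(np.int64), degenerate


def scan_pairs(
    dataset: GenotypeDataset,
    eligible_pairs: Iterable[tuple[str, str]],
    screen_alpha: float = 1e-4,
) -> list[SnpPairResult]:
    """Run the two-stage scan over the given SNP-id pairs.

    Every pair is screened; pairs with screen p <= ``screen_alpha`` also get
    the logistic follow-up. Per-pair failures are carried in ``status``.
    Output is sorted by Wald p (follow-ups first), then screen p, then pair
    ids, so it is deterministic given the input set.
    """
    if not (0 <= screen_alpha <= 1):
        raise ValueError("screen_alpha must be in [0, 1]")
    vindex = dataset.variant_index()
    keys = _canonical_keys(dataset)
    pheno = dataset.phenotypes
    d = dataset.dosages

    ordered: list[tuple[str, str]] = []
    for raw_a, raw_b in eligible_pairs:
        if keys[raw_a] <= keys[raw_b]:
            ordered.append((raw_a, raw_b))
        else:
            ordered.append((raw_b, raw_a))
    if not ordered:
        return []
    ai = np.array([vindex[a] for a, _ in ordered], dtype=np.intp)
    bi = np.array([vindex[b] for _, b in ordered], dtype=np.intp)

    # one-hot genotype (and genotype-by-phenotype) indicators; missing
    # genotypes and phenotypes vanish from every cell automatically
    onehot = np.stack([(d == g).astype(np.float64) for g in (0, 1, 2)])
    pheno_mask = np.stack(
        [(pheno == PHENO_CONTROL), (pheno == PHENO_CASE)]
    ).astype(np.float64)
    onehot_pheno = onehot[:, None, :, :] * pheno_mask[None, :, :, None]

    results: list[SnpPairResult] = []
    block = 8192
    for start in range(0, len(ordered), block):
        sl = slice(start, min(start + block, len(ordered)))
        tau_b, n_used_b, _counts, degen_b = _screen_block(
            onehot_pheno, onehot, ai[sl], bi[sl]
        )
        p_screen_b = chi2.sf(tau_b, df=4)
        for off, (vid_a, vid_b) in enumerate(ordered[sl]):
            if degen_b[off]:
                results.append(
                    SnpPairResult(vid_a, vid_b, np.nan, np.nan, None, None, None,
                                  None, int(n_used_b[off]), STATUS_DEGENERATE)
                )
                continue
            tau = float(tau_b[off])
            p_screen = float(p_screen_b[off])
            if p_screen <= screen_alpha:
                fit = logistic_interaction_test(
                    d[:, ai[sl][off]], d[:, bi[sl][off]], pheno
                )
                results.append(SnpPairResult(vid_a, vid_b, tau, p_screen, **fit))
            else:
                results.append(
                    SnpPairResult(vid_a, vid_b, tau, p_screen, None, None, None,
                                  None, int(n_used_b[off]), STATUS_SCREEN_ONLY)
                )
    results.sort(
        key=lambda r: (
            r.p_wald if r.p_wald is not None else np.inf,
            r.p_screen if np.isfinite(r.p_screen) else np.inf,
            r.snp_a,
            r.snp_b,
        )
    )
    return results
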