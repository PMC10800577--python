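"""Independent reference implementations used only by the tests.

Each oracle recomputes a quantity by a different route than the library
(direct enumeration, brute force, iterative proportional fitting, grid
search) so that agreement is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln


# --- exact HWE by direct enumeration ---------------------------------------


def hwe_enum_distribution(n_minor: int, n_total: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional het-count distribution from explicit log-factorials.

    P(N_het = h | n, n_minor) = n! / (n_mm! h! n_MM!) * 2^h * n_minor! *
    n_major! / (2n)! with n_mm = (n_minor - h)/2 homozygous-minor and
    n_MM = (n_major - h)/2 homozygous-major individuals.
    """
    n_major = 2 * n_total - n_minor
    h0 = n_minor % 2
    hets = np.arange(h0, min(n_minor, n_major) + 1, 2)
    n_mm = (n_minor - hets) // 2
    n_MM = (n_major - hets) // 2
    logp = (
        gammaln(n_total + 1)
        - gammaln(n_mm + 1)
        - gammaln(hets + 1)
        - gammaln(n_MM + 1)
        + hets * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(n_major + 1)
        - gammaln(2 * n_total + 1)
    )
    p = np.exp(logp - logp.max())
    return hets, p / p.sum()


def hwe_enum_pvalue(n_hom1: int, n_het: int, n_hom2: int) -> float:
    n_total = n_hom1 + n_het + n_hom2
    n_minor = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    hets, probs = hwe_enum_distribution(n_minor, n_total)
    p_obs = float(probs[hets == n_het][0])
    return min(float(probs[probs <= p_obs * (1 + 1e-12)].sum()), 1.0)


# --- Kirkwood superposition, cell by cell ----------------------------------


def ksa_cell_by_cell(counts: np.ndarray) -> np.ndarray:
    """KSA fitted probabilities computed with explicit loops per cell."""
    n = counts.sum()
    p = counts / n
    fitted = np.zeros((3, 3, 2))
    for i in range(3):
        for j in range(3):
            for k in range(2):
                p_ij = p[i, j, :].sum()
                p_ik = p[i, :, k].sum()
                p_jk = p[:, j, k].sum()
                p_i = p[i, :, :].sum()
                p_j = p[:, j, :].sum()
                p_k = p[:, :, k].sum()
                den = p_i * p_j * p_k
                fitted[i, j, k] = (p_ij * p_ik * p_jk / den) if den > 0 else 0.0
    total = fitted.sum()
    return fitted / total


def ksa_tau(counts: np.ndarray) -> float:
    """Screening statistic from the cell-by-cell KSA fit."""
    n = counts.sum()
    fitted = ksa_cell_by_cell(counts)
    tau = 0.0
    for i in range(3):
        for j in range(3):
            for k in range(2):
                c = counts[i, j, k]
                if c > 0:
                    tau += 2.0 * c * (np.log(c / n) - np.log(fitted[i, j, k]))
    return tau


# --- exact homogeneous-association LR via IPF ------------------------------


def ipf_homogeneous_association(
    counts: np.ndarray, max_iter: int = 2000, tol: float = 1e-10
) -> np.ndarray:
    """MLE expected counts of the no-three-way-interaction log-linear model.

    Iterative proportional fitting to the three observed two-way margins.
    """
    n = counts.astype(float)
    m = np.ones_like(n)
    m *= n.sum() / m.sum()
    target_ij = n.sum(axis=2)
    target_ik = n.sum(axis=1)
    target_jk = n.sum(axis=0)
    for _ in range(max_iter):
        cur = m.sum(axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            m *= np.where(cur > 0, target_ij / np.where(cur > 0, cur, 1), 0)[:, :, None]
        cur = m.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            m *= np.where(cur > 0, target_ik / np.where(cur > 0, cur, 1), 0)[:, None, :]
        cur = m.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            m *= np.where(cur > 0, target_jk / np.where(cur > 0, cur, 1), 0)[None, :, :]
        err = max(
            np.abs(m.sum(axis=2) - target_ij).max(),
            np.abs(m.sum(axis=1) - target_ik).max(),
            np.abs(m.sum(axis=0) - target_jk).max(),
        )
        if err < tol:
            break
    return m


def exact_lr_statistic(counts: np.ndarray) -> float:
    """2 * sum n log(n/m) against the IPF homogeneous-association fit."""
    m = ipf_homogeneous_association(counts)
    stat = 0.0
    for idx in np.ndindex(3, 3, 2):
        c = counts[idx]
        if c > 0:
            stat += 2.0 * c * np.log(c / m[idx])
    return stat


# --- grid-search logistic MLE ----------------------------------------------


def logistic_loglik(X: np.ndarray, y: np.ndarray, betas: np.ndarray) -> np.ndarray:
    """Log-likelihood for each row of ``betas`` (k columns)."""
    eta = X @ betas.T  # (n, B)
    return (y[:, None] * eta - np.logaddexp(0.0, eta)).sum(axis=0)


def grid_search_logistic(
    X: np.ndarray, y: np.ndarray, half_width: float = 4.0, points: int = 9, rounds: int = 8
) -> np.ndarray:
    """Coarse-to-fine grid search maximising the logistic log-likelihood.

    Each round lays a ``points``-per-axis grid over a box centred on the
    current best point, then shrinks the box. Converges well inside 1e-2 of
    the MLE for well-posed 4-parameter problems.
    """
    k = X.shape[1]
    centre = np.zeros(k)
    width = half_width
    for _ in range(rounds):
        axes = [np.linspace(c - width, c + width, points) for c in centre]
        mesh = np.meshgrid(*axes, indexing="ij")
        grid = np.stack([m.ravel() for m in mesh], axis=1)
        ll = logistic_loglik(X, y, grid)
        centre = grid[int(np.argmax(ll))]
        width *= 2.0 / (points - 1)  # keep neighbours of the best point in the next box
    return centre


# --- brute-force Benjamini-Hochberg ----------------------------------------


def bh_brute_force(pvalues: list[float], m: int, alpha: float) -> tuple[float, int]:
    """Textbook step-up BH by explicit rank check."""
    p = sorted(pvalues)
    best_k = 0
    for k in range(1, len(p) + 1):
        if p[k - 1] <= k * alpha / m:
            best_k = k
    if best_k == 0:
        return 0.0, 0
    return best_k * alpha / m, best_k


# --- brute-force gene-pair collapse ----------------------------------------


def collapse_brute_force(rows, assignment):
    """Min-p collapse over an explicit list of (snp_a, snp_b, p, or) rows."""
    contributions: dict[tuple[str, str], list] = {}
    for snp_a, snp_b, p, or_value in rows:
        for ga in assignment[snp_a]:
            for gb in assignment[snp_b]:
                if ga == gb:
                    continue
                key = tuple(sorted((ga, gb)))
                contributions.setdefault(key, []).append((p, snp_a, snp_b, or_value))
    out = {}
    for key, items in contributions.items():
        items.sort()
        out[key] = items[0]
    return out


# --- PLINK bed bit decoding ------------------------------------------------


def decode_bed_byte(byte: int, n: int = 4) -> list[int]:
    """Two-bit genotype codes of one bed byte, low bits first (PLINK order)."""
    return [(byte >> (2 * i)) & 0b11 for i in range(n)]
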