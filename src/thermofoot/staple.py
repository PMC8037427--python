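"""STAPLE: simultaneous truth and performance level estimation.

Fuses binary segmentations from several imperfect raters into a
probabilistic estimate of the hidden true segmentation while jointly
estimating each rater's sensitivity ``p_j`` and specificity ``q_j`` by
expectation-maximization.

With rater decisions ``D_ij`` (pixel ``i``, rater ``j``) and foreground
prior ``pi_i``:

E-step::

    a_i = pi_i * prod_j p_j^D_ij (1-p_j)^(1-D_ij)
    b_i = (1-pi_i) * prod_j (1-q_j)^D_ij q_j^(1-D_ij)
    W_i = a_i / (a_i + b_i)

M-step::

    p_j = sum_i W_i D_ij / sum_i W_i
    q_j = sum_i (1-W_i)(1-D_ij) / sum_i (1-W_i)

Products are accumulated in log-space so many raters cannot underflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["StapleResult", "run_staple", "threshold_consensus"]

_EPS = 1e-6  # boundary clamp for degenerate (all-0 / all-1) raters


@dataclass(frozen=True)
class StapleResult:
    W: np.ndarray  # posterior foreground probability per pixel
    p: np.ndarray  # per-rater sensitivity
    q: np.ndarray  # per-rater specificity
    n_em_iters: int
    converged: bool
    log_likelihood: tuple[float, ...] = ()


def run_staple(
    stack: list[np.ndarray],
    prior: float | np.ndarray | None = None,
    max_iters: int = 100,
    tol: float = 1e-6,
) -> StapleResult:
    """Run STAPLE EM on a stack of aligned binary rater masks.

    ``prior`` is the foreground prior probability: a scalar, a per-pixel
    map, or None to use the mean foreground fraction across raters (the
    common practice when no atlas prior exists).  Iterates until the
    largest change in any (p, q) parameter falls below ``tol``.
    """
    if len(stack) < 2:
        raise ValueError("STAPLE needs at least 2 raters")
    shape = np.asarray(stack[0]).shape
    d = np.stack([np.asarray(m) for m in stack]).reshape(len(stack), -1).astype(float)
    if any(np.asarray(m).shape != shape for m in stack):
        raise ValueError("all rater masks must share one shape")
    if not np.isin(d, (0.0, 1.0)).all():
        raise ValueError("rater masks must be strictly binary")
    n_raters, n_px = d.shape
    for j in range(n_raters):
        if d[j].min() == d[j].max():
            warnings.warn(
                f"rater {j} is all-{int(d[j][0])}; its performance parameters "
                "are clamped away from the boundary",
                stacklevel=2,
            )
    if prior is None:
        prior = float(d.mean())
    pi = np.asarray(prior, float).reshape(-1)
    if pi.size not in (1, n_px):
        raise ValueError("prior must be a scalar or match the mask size")
    if np.any(pi <= 0) or np.any(pi >= 1):
        raise ValueError("prior probabilities must lie strictly in (0, 1)")
    log_pi_f = np.log(pi)
    log_pi_b = np.log1p(-pi)

    p = np.full(n_raters, 1.0 - 1e-4)
    q = np.full(n_raters, 1.0 - 1e-4)
    ll_trace: list[float] = []
    converged = False
    it = 0

    def e_step(p, q):
        log_a = log_pi_f + np.log(p) @ d + np.log1p(-p) @ (1.0 - d)
        log_b = log_pi_b + np.log1p(-q) @ d + np.log(q) @ (1.0 - d)
        m = np.maximum(log_a, log_b)
        ll = float(np.sum(m + np.log(np.exp(log_a - m) + np.exp(log_b - m))))
        return 1.0 / (1.0 + np.exp(log_b - log_a)), ll

    for it in range(1, max_iters + 1):
        w, ll = e_step(p, q)
        ll_trace.append(ll)
        # M-step
        sw = w.sum()
        swc = n_px - sw
        p_new = np.clip((d @ w) / max(sw, _EPS), _EPS, 1.0 - _EPS)
        q_new = np.clip(((1.0 - d) @ (1.0 - w)) / max(swc, _EPS), _EPS, 1.0 - _EPS)
        delta = max(np.abs(p_new - p).max(), np.abs(q_new - q).max())
        p, q = p_new, q_new
        if delta < tol:
            converged = True
            break
    # final E-step so W is the posterior under the returned parameters
    w, ll = e_step(p, q)
    ll_trace.append(ll)
    return StapleResult(
        W=w.reshape(shape),
        p=p,
        q=q,
        n_em_iters=it,
        converged=converged,
        log_likelihood=tuple(ll_trace),
    )


def threshold_consensus(res: StapleResult, level: float = 0.5) -> np.ndarray:
    """Binarize the fused probability map; ties at the level go foreground."""
    if not (0.0 < level < 1.0):
        raise ValueError("threshold level must lie in (0, 1)")
    return (res.W >= level).astype(np.uint8)
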