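"""Model-comparison statistics for censored risk prediction.

Harrell's c-index over comparable pairs (with an asymptotic U-statistic
standard error and an optional seeded bootstrap), the fraction of new
information 1 - chi2_ref/chi2_alt, the heuristic shrinkage factor
(chi2 - df)/chi2, and predicted-risk distribution summaries.
"""

from __future__ import annotations

import numpy as np


def _validate_survival(time, event, score):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    score = np.asarray(score, dtype=float)
    if not (time.shape == event.shape == score.shape):
        raise ValueError("time, event and score must have equal length")
    if not np.all(np.isfinite(score)):
        raise ValueError("scores must be finite")
    return time, event, score


def _concordance_counts(time, event, score, chunk: int = 512):
    """Pairwise concordant/comparable totals plus per-subject sums.

    Comparable pairs: the earlier time is an event (classic censoring rule);
    pairs tied on time count when exactly one is an event (the event member
    should score higher), and both-event time ties contribute half credit
    (the score-tie convention). Score ties always earn half credit.
    """
    n = time.size
    C = np.zeros(n)  # concordance credit involving subject i
    M = np.zeros(n)  # comparable pairs involving subject i
    ev_idx = np.flatnonzero(event == 1)
    for start in range(0, ev_idx.size, chunk):
        idx = ev_idx[start : start + chunk]
        ti = time[idx][:, None]
        si = score[idx][:, None]
        # strictly later times, or same-time censored partners
        comp = (time[None, :] > ti) | ((time[None, :] == ti) & (event[None, :] == 0))
        cred = np.where(si > score[None, :], 1.0, np.where(si == score[None, :], 0.5, 0.0))
        cred = cred * comp
        M[idx] += comp.sum(axis=1)
        M += comp.sum(axis=0)
        C[idx] += cred.sum(axis=1)
        C += cred.sum(axis=0)
    # both-event exact time ties: half credit each way
    t_ev = time[ev_idx]
    order = np.argsort(t_ev, kind="stable")
    sorted_t = t_ev[order]
    uniq, counts = np.unique(sorted_t, return_counts=True)
    pos = 0
    for u, c in zip(uniq, counts):
        if c > 1:
            members = ev_idx[order[pos : pos + c]]
            M[members] += c - 1
            C[members] += 0.5 * (c - 1)
        pos += c
    return C, M


def harrell_c(time, event, score, ci_method: str = "ustat", n_boot: int = 200, seed: int = 0):
    """Harrell's concordance index with 95 % CI.

    Higher score must mean higher risk. Returns ``(c, se, (lo, hi))``.
    ``ci_method='ustat'`` uses the infinitesimal-jackknife variance of the
    pairwise U-statistic; ``'bootstrap'`` resamples subjects with a seeded RNG.
    """
    time, event, score = _validate_survival(time, event, score)
    C, M = _concordance_counts(time, event, score)
    total_m = M.sum() / 2.0
    if total_m == 0:
        raise ValueError("no comparable pairs (no events, or all times tied)")
    c = (C.sum() / 2.0) / total_m
    if ci_method == "ustat":
        psi = (C - c * M) / total_m
        se = float(np.sqrt(np.sum(psi**2)))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = time.size
        reps = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            Cb, Mb = _concordance_counts(time[idx], event[idx], score[idx])
            mb = Mb.sum() / 2.0
            if mb > 0:
                reps.append((Cb.sum() / 2.0) / mb)
        se = float(np.std(reps, ddof=1))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    lo = max(c - 1.959963984540054 * se, 0.0)
    hi = min(c + 1.959963984540054 * se, 1.0)
    return float(c), se, (float(lo), float(hi))


def fraction_new_information(chi2_ref: float, chi2_alt: float) -> float:
    """FNI = 1 - chi2_ref / chi2_alt: the share of the expanded model's
    prognostic information that the reference model lacks."""
    if chi2_ref <= 0 or chi2_alt <= 0:
        raise ValueError("chi-square statistics must be positive")
    return 1.0 - chi2_ref / chi2_alt


def shrinkage_factor(chi2: float, df: float) -> float:
    """Heuristic shrinkage (chi2 - df)/chi2: values near 1 mean little
    over-fitting optimism in the estimated coefficients."""
    if chi2 <= 0:
        raise ValueError("chi-square must be positive")
    return (chi2 - df) / chi2


def risk_summary(risks) -> dict[str, float]:
    """Median and IQR of predicted risks, expressed in percent."""
    risks = np.asarray(risks, dtype=float)
    if risks.size == 0:
        raise ValueError("no risks supplied")
    if np.any((risks <= 0) | (risks >= 1)):
        raise ValueError("risks must lie in (0,1)")
    q1, med, q3 = np.percentile(risks, [25, 50, 75], method="linear")
    return {
        "median_pct": 100.0 * med,
        "q1_pct": 100.0 * q1,
        "q3_pct": 100.0 * q3,
    }
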