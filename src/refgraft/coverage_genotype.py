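"""Read-depth copy-number genotyping of integrated insertions.

Pipeline per sample: count read midpoints in 50-bp windows, mark windows
"alignable" when low-quality reads (mapq <= 1) are at most 40% of coverage,
correct GC bias by dividing by a per-2%-GC-bin standard coverage (10%
truncated mean), then average normalised coverage over each insertion's
alignable windows to obtain one value x_n per sample and insertion.

Across samples, x_n is modelled as Normal(a + b * S_n, 1/c) where
S_n = sum_{j=1..A_n} z_nj is the summed haploid copy number, z_nj iid
multinomial(theta_0..theta_M), A_n the chromosome count (2 for autosomes).
Parameters (a, b, c, theta) are fitted per insertion by MAP-EM with priors
a ~ Normal(0, lambda_a), log b ~ Normal(0, lambda_b), c ~ Gamma(lambda_c),
theta ~ Dirichlet(lambda_theta).  A sample's copy number is called when the
posterior of S exceeds 0.8, otherwise left missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

WINDOW_WIDTH = 50
FLANK = 200  # GC flank: 400 bp starting 200 bp upstream of window start
LOWQ_MAPQ = 1
LOWQ_MAX_FRAC = 0.40
GC_BIN_WIDTH = 0.02
TRUNC_FRAC = 0.10
MIN_BIN_WINDOWS = 100
MIN_COVERED_BP = 50
MIN_COVERED_FRAC = 0.30
POSTERIOR_THRESHOLD = 0.8

DEFAULT_M = 10
LAMBDA_A = 8.0
LAMBDA_B = 16.0
LAMBDA_C = 1.0
LAMBDA_THETA = 1.0
RESTART_A = (0.0, 0.4, 0.8)
MAX_ITER = 500
REL_TOL = 1e-8
C_MAX = 1e6  # variance floor 1e-6
B_WARMUP_ITER = 25  # iterations with the slope b held at its restart value


# ---------------------------------------------------------------------------
# Windowed coverage and GC normalisation
# ---------------------------------------------------------------------------


def _gc_cumsum(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    return np.concatenate([[0], np.cumsum(is_gc)])


def window_coverage(
    reads,
    reference: Mapping[str, str],
    width: int = WINDOW_WIDTH,
    lowq_mapq: int = LOWQ_MAPQ,
    lowq_max_frac: float = LOWQ_MAX_FRAC,
) -> pd.DataFrame:
    """Tabulate read-midpoint coverage in fixed windows.

    ``reads`` is a BAM/SAM path, or a DataFrame/TSV path with columns
    (chrom, midpoint, mapq).  A read is assigned to the single window
    containing its midpoint.  Windows with no reads are kept (total 0, not
    alignable).  Returns one row per window: ref_name, start, total_count,
    lowq_count, gc_fraction, alignable.
    """
    if isinstance(reads, str) and reads.endswith((".bam", ".sam", ".cram")):
        import pysam

        rows = []
        with pysam.AlignmentFile(reads) as fh:
            for rec in fh:
                if rec.is_unmapped:
                    continue
                mid = (rec.reference_start + rec.reference_end) // 2
                rows.append((rec.reference_name, mid, rec.mapping_quality))
        table = pd.DataFrame(rows, columns=["chrom", "midpoint", "mapq"])
    elif isinstance(reads, str):
        table = pd.read_csv(reads, sep="\t")
    else:
        table = reads

    frames = []
    for ref_name, seq in reference.items():
        n_win = max(1, -(-len(seq) // width))
        starts = np.arange(n_win, dtype=np.int64) * width
        sub = table[table["chrom"] == ref_name]
        idx = (sub["midpoint"].to_numpy() // width).astype(np.int64)
        in_range = (idx >= 0) & (idx < n_win)
        idx = idx[in_range]
        lowq = sub["mapq"].to_numpy()[in_range] <= lowq_mapq
        total = np.bincount(idx, minlength=n_win)
        low = np.bincount(idx[lowq], minlength=n_win)
        cum = _gc_cumsum(seq)
        f0 = np.clip(starts - FLANK, 0, len(seq))
        f1 = np.clip(starts + FLANK, 0, len(seq))
        span = np.maximum(f1 - f0, 1)
        gc = (cum[f1] - cum[f0]) / span
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(total > 0, low / np.maximum(total, 1), 1.0)
        alignable = (total > 0) & (ratio <= lowq_max_frac)
        frames.append(
            pd.DataFrame(
                {
                    "ref_name": ref_name,
                    "start": starts,
                    "total_count": total,
                    "lowq_count": low,
                    "gc_fraction": gc,
                    "alignable": alignable,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def windows_from_counts(
    counts: pd.DataFrame,
    reference: Mapping[str, str],
    width: int = WINDOW_WIDTH,
    lowq_max_frac: float = LOWQ_MAX_FRAC,
) -> pd.DataFrame:
    """Attach GC fractions and the alignable flag to precomputed window counts.

    ``counts`` has columns (ref_name, start, total_count, lowq_count), one
    row per window, as produced by depth pre-tabulation or the simulator.
    """
    frames = []
    for ref_name, sub in counts.groupby("ref_name", sort=False):
        seq = reference[ref_name]
        cum = _gc_cumsum(seq)
        starts = sub["start"].to_numpy()
        f0 = np.clip(starts - FLANK, 0, len(seq))
        f1 = np.clip(starts + FLANK, 0, len(seq))
        gc = (cum[f1] - cum[f0]) / np.maximum(f1 - f0, 1)
        total = sub["total_count"].to_numpy()
        low = sub["lowq_count"].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(total > 0, low / np.maximum(total, 1), 1.0)
        out = sub.copy()
        out["gc_fraction"] = gc
        out["alignable"] = (total > 0) & (ratio <= lowq_max_frac)
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


@dataclass
class GcStandardTable:
    """Per-GC-bin standard coverage; NaN marks bins with too few windows."""

    bin_width: float
    standards: np.ndarray  # length ceil(1/bin_width)

    def bin_of(self, gc: np.ndarray) -> np.ndarray:
        n = len(self.standards)
        return np.minimum((np.asarray(gc) / self.bin_width).astype(int), n - 1)

    def standard_for(self, gc: np.ndarray) -> np.ndarray:
        return self.standards[self.bin_of(gc)]


def truncated_mean(values: np.ndarray, trim: float = TRUNC_FRAC) -> tuple[float, int]:
    """Mean after trimming ``trim`` of the values from each tail.

    Returns (mean, n_remaining); (nan, 0) for empty input.
    """
    v = np.sort(np.asarray(values, dtype=float))
    k = int(math.floor(trim * len(v)))
    kept = v[k : len(v) - k] if k > 0 else v
    if len(kept) == 0:
        return float("nan"), 0
    return float(kept.mean()), len(kept)


def gc_standard(
    windows: pd.DataFrame,
    bin_width: float = GC_BIN_WIDTH,
    trim: float = TRUNC_FRAC,
    min_windows: int = MIN_BIN_WINDOWS,
) -> GcStandardTable:
    """Standard coverage per GC bin from alignable windows.

    The standard is the 10% truncated mean of window coverage in the bin; a
    bin is valid only when at least ``min_windows`` windows remain after
    truncation and the standard is positive.
    """
    n_bins = int(math.ceil(1.0 / bin_width))
    standards = np.full(n_bins, np.nan)
    align = windows[windows["alignable"]]
    bins = np.minimum(
        (align["gc_fraction"].to_numpy() / bin_width).astype(int), n_bins - 1
    )
    for b in np.unique(bins):
        mean, n_kept = truncated_mean(
            align["total_count"].to_numpy()[bins == b], trim
        )
        if n_kept >= min_windows and mean > 0:
            standards[b] = mean
    return GcStandardTable(bin_width, standards)


def normalize(windows: pd.DataFrame, table: GcStandardTable) -> pd.DataFrame:
    """Divide window coverage by the GC-bin standard (NaN for invalid bins)."""
    out = windows.copy()
    std = table.standard_for(out["gc_fraction"].to_numpy())
    with np.errstate(invalid="ignore", divide="ignore"):
        out["normalized"] = out["total_count"].to_numpy() / std
    return out


def insertion_coverage(
    windows: pd.DataFrame,
    insertion_intervals: Mapping[str, tuple[str, int, int]],
    width: int = WINDOW_WIDTH,
    min_bp: int = MIN_COVERED_BP,
    min_frac: float = MIN_COVERED_FRAC,
) -> pd.Series:
    """Mean normalised coverage per insertion (NaN when under-covered).

    Only alignable windows with a valid normalised value that lie fully
    inside the insertion interval contribute; the value is invalidated when
    those windows cover < ``min_bp`` or < ``min_frac`` of the insertion.
    """
    ref_sizes = windows.groupby("ref_name")["start"].max()
    usable = windows[windows["alignable"] & windows["normalized"].notna()]
    by_ref = {r: g for r, g in usable.groupby("ref_name")}
    values: dict[str, float] = {}
    for ins_id, (ref_name, start, end) in insertion_intervals.items():
        if ref_name not in ref_sizes.index:
            raise KeyError(f"insertion {ins_id}: unknown chromosome {ref_name!r}")
        g = by_ref.get(ref_name)
        if g is None:
            values[ins_id] = float("nan")
            continue
        s = g["start"].to_numpy()
        inside = (s >= start) & (s + width <= end)
        covered = int(inside.sum()) * width
        if covered < min_bp or covered < min_frac * (end - start):
            values[ins_id] = float("nan")
        else:
            values[ins_id] = float(g["normalized"].to_numpy()[inside].mean())
    return pd.Series(values, name="x")


# ---------------------------------------------------------------------------
# EM / MAP copy-number model
# ---------------------------------------------------------------------------


@dataclass
class CopyNumberModel:
    a: float
    b: float
    c: float
    theta: np.ndarray  # haploid copy-number probabilities, length M+1
    M: int = DEFAULT_M
    lambda_a: float = LAMBDA_A
    lambda_b: float = LAMBDA_B
    lambda_c: float = LAMBDA_C
    lambda_theta: float = LAMBDA_THETA
    loglik: float = float("-inf")  # penalized (MAP) objective at convergence
    accepted: bool = False
    init_used: float = float("nan")
    n_used: int = 0
    converged: bool = False
    objective_trace: list = field(default_factory=list)


def _prior_over_S(theta: np.ndarray, A: int) -> np.ndarray:
    """Distribution of S = sum of A iid multinomial(theta) haploid copies."""
    if A == 0:
        return np.array([1.0])
    p = theta
    for _ in range(A - 1):
        p = np.convolve(p, theta)
    return p


def _log_priors(a, b, c, theta, la, lb, lc, lt) -> float:
    lp = -(a * a) / (2 * la) - (math.log(b) ** 2) / (2 * lb)
    lp += (lc - 1) * math.log(c) - c
    if lt != 1.0:
        lp += (lt - 1) * float(np.sum(np.log(np.clip(theta, 1e-300, None))))
    return lp


def _expected_haploid_counts(gamma: np.ndarray, theta: np.ndarray, A: int) -> np.ndarray:
    """E[# of haploid draws equal to k] summed over samples of chromosome count A.

    ``gamma`` is (n, A*M+1) posterior over S.  For diploids the exchangeable
    decomposition is used: E[#{j: z_j = k} | S] = 2 theta_k theta_{S-k} / p2(S).
    """
    M = len(theta) - 1
    if A == 0 or gamma.size == 0:
        return np.zeros(M + 1)
    if A == 1:
        return gamma.sum(axis=0)
    p2 = _prior_over_S(theta, 2)
    counts = np.zeros(M + 1)
    g_tot = gamma.sum(axis=0)  # per-S totals
    for S in range(2 * M + 1):
        if g_tot[S] <= 0 or p2[S] <= 0:
            continue
        ks = np.arange(max(0, S - M), min(M, S) + 1)
        w = theta[ks] * theta[S - ks]
        w_sum = w.sum()
        if w_sum <= 0:
            continue
        counts[ks] += g_tot[S] * 2.0 * w / w_sum
    return counts


def _init_theta(
    x: np.ndarray, A: np.ndarray, a0: float, b0: float, M: int
) -> np.ndarray:
    """Data-driven starting point for theta.

    Each sample is assigned its nearest summed copy number under the initial
    (a, b), split evenly into haploid copies; a flat pseudo-count keeps all
    categories reachable.  A uniform theta would leave the first posteriors
    prior-dominated (c starts at 1, a nearly flat likelihood) and push b into
    a halved-slope local optimum.
    """
    counts = np.full(M + 1, 0.5)
    for xi, Ai in zip(x, A):
        if Ai == 0:
            continue
        s_hat = int(np.clip(round((xi - a0) / b0), 0, Ai * M))
        z1 = s_hat // Ai if Ai else 0
        counts[z1] += 1
        if Ai == 2:
            counts[s_hat - z1] += 1
    return counts / counts.sum()


def _em_once(
    x: np.ndarray,
    A: np.ndarray,
    a0: float,
    b0: float,
    c0: float,
    M: int,
    la: float,
    lb: float,
    lc: float,
    lt: float,
    max_iter: int,
    rel_tol: float,
) -> CopyNumberModel:
    n = len(x)
    a, b, c = a0, b0, c0
    theta = _init_theta(x, A, a0, b0, M)
    groups = {int(v): np.where(A == v)[0] for v in np.unique(A)}
    trace: list[float] = []
    converged = False

    for _ in range(max_iter):
        # E-step: posterior over S per chromosome-count group
        total_ll = 0.0
        gammas: dict[int, np.ndarray] = {}
        for Ag, idx in groups.items():
            S = np.arange(Ag * M + 1)
            logp_S = np.log(np.clip(_prior_over_S(theta, Ag), 1e-300, None))
            mu = a + b * S
            ll = (
                0.5 * math.log(c / (2 * math.pi))
                - 0.5 * c * (x[idx, None] - mu[None, :]) ** 2
            )
            logw = logp_S[None, :] + ll
            norm = logsumexp(logw, axis=1)
            total_ll += float(norm.sum())
            gammas[Ag] = np.exp(logw - norm[:, None])

        obj = total_ll + _log_priors(a, b, c, theta, la, lb, lc, lt)
        trace.append(obj)
        if len(trace) > B_WARMUP_ITER + 2:
            prev = trace[-2]
            if abs(obj - prev) <= rel_tol * (abs(prev) + 1.0):
                converged = True
                break

        # sufficient statistics for the linear part
        sx = float(x.sum())
        sxx = float((x * x).sum())
        es1 = 0.0  # sum_n E[S_n]
        es2 = 0.0  # sum_n E[S_n^2]
        exs = 0.0  # sum_n x_n E[S_n]
        for Ag, idx in groups.items():
            S = np.arange(Ag * M + 1, dtype=float)
            g = gammas[Ag]
            eS = g @ S
            es1 += float(eS.sum())
            es2 += float((g @ (S * S)).sum())
            exs += float((x[idx] * eS).sum())

        def sse(a_, b_):
            return (
                sxx
                - 2 * a_ * sx
                - 2 * b_ * exs
                + n * a_ * a_
                + 2 * a_ * b_ * es1
                + b_ * b_ * es2
            )

        def a_star(b_):
            return c * (sx - b_ * es1) / (c * n + 1.0 / la)

        def neg_obj_logb(logb_):
            b_ = math.exp(logb_)
            a_ = a_star(b_)
            return (
                0.5 * c * sse(a_, b_)
                + a_ * a_ / (2 * la)
                + logb_ * logb_ / (2 * lb)
            )

        # ECM schedule: hold b during warm-up so c and theta sharpen first
        # (updating b against prior-dominated posteriors at c ~ 1 drags the
        # slope into a collapsed local optimum); each block update ascends
        # the penalized objective, so monotonicity is preserved throughout.
        if len(trace) > B_WARMUP_ITER:
            res = minimize_scalar(
                neg_obj_logb, bounds=(-5.0, 5.0), method="bounded"
            )
            # never move downhill: keep the old b if the line search lost
            if res.fun <= neg_obj_logb(math.log(b)):
                b = math.exp(res.x)
        a = a_star(b)

        c = (n / 2.0 + lc - 1.0) / (sse(a, b) / 2.0 + 1.0)
        c = min(max(c, 1e-12), C_MAX)

        m = np.zeros(M + 1)
        for Ag, idx in groups.items():
            m += _expected_haploid_counts(gammas[Ag], theta, Ag)
        m += lt - 1.0
        m = np.clip(m, 0.0, None)
        if m.sum() > 0:
            theta = m / m.sum()

    model = CopyNumberModel(
        a=a,
        b=b,
        c=c,
        theta=theta,
        M=M,
        lambda_a=la,
        lambda_b=lb,
        lambda_c=lc,
        lambda_theta=lt,
        loglik=trace[-1] if trace else float("-inf"),
        accepted=(abs(a) <= 0.75 and 0.6 <= b <= 1.4),
        init_used=a0,
        n_used=n,
        converged=converged,
        objective_trace=trace,
    )
    return model


def fit_copy_number(
    x_values: Sequence[float],
    A_values: Sequence[int],
    M: int = DEFAULT_M,
    lambda_a: float = LAMBDA_A,
    lambda_b: float = LAMBDA_B,
    lambda_c: float = LAMBDA_C,
    lambda_theta: float = LAMBDA_THETA,
    restarts_a: Sequence[float] = RESTART_A,
    init_b: float = 1.0,
    init_c: float = 1.0,
    max_iter: int = MAX_ITER,
    rel_tol: float = REL_TOL,
) -> CopyNumberModel:
    """MAP-EM fit of the copy-number model for one insertion.

    Samples with NaN coverage are excluded from fitting.  The EM is run from
    three deterministic initialisations a = (0, 0.4, 0.8) with b = 1, c = 1;
    the restart with the best penalized objective wins and the acceptance
    band |a| <= 0.75 and 0.6 <= b <= 1.4 is then evaluated on it.  Selecting
    by objective *before* the band matters: an out-of-band truth (say a
    genuine offset of 0.9) often has an in-band mirror solution with every
    copy number shifted by one; preferring accepted restarts would silently
    return that distorted model instead of flagging the locus.
    """
    x = np.asarray(x_values, dtype=float)
    A = np.asarray(A_values, dtype=int)
    ok = ~np.isnan(x)
    x, A = x[ok], A[ok]
    if len(x) < 2:
        raise ValueError("need at least 2 valid coverage values to fit")

    fits = [
        _em_once(
            x, A, a0, init_b, init_c, M,
            lambda_a, lambda_b, lambda_c, lambda_theta, max_iter, rel_tol,
        )
        for a0 in restarts_a
    ]
    return max(fits, key=lambda f: f.loglik)


def posterior_over_S(
    model: CopyNumberModel, x: float, A: int
) -> np.ndarray:
    """Posterior P(S | x) on support 0..A*M (point mass at 0 when A = 0)."""
    S = np.arange(A * model.M + 1)
    logp = np.log(np.clip(_prior_over_S(model.theta, A), 1e-300, None))
    mu = model.a + model.b * S
    logw = logp - 0.5 * model.c * (x - mu) ** 2
    w = np.exp(logw - logw.max())
    return w / w.sum()


def call_copy_numbers(
    model: CopyNumberModel,
    x_values: Sequence[float],
    A_values: Sequence[int],
    threshold: float = POSTERIOR_THRESHOLD,
) -> pd.DataFrame:
    """Posterior copy-number calls; S is NaN unless max posterior > threshold.

    Samples with invalid (NaN) coverage get a missing call.  With A = 0 the
    call is S = 0 with posterior 1 regardless of coverage.
    """
    rows = []
    for x, A in zip(x_values, A_values):
        A = int(A)
        if A == 0:
            rows.append((0.0, 1.0))
            continue
        if np.isnan(x):
            rows.append((float("nan"), float("nan")))
            continue
        post = posterior_over_S(model, float(x), A)
        s_hat = int(np.argmax(post))
        p_max = float(post[s_hat])
        rows.append((float(s_hat) if p_max > threshold else float("nan"), p_max))
    return pd.DataFrame(rows, columns=["S", "posterior_max"])


def apply_fitted_model(
    model: CopyNumberModel,
    new_x_values: Sequence[float],
    new_A_values: Sequence[int],
    threshold: float = POSTERIOR_THRESHOLD,
) -> pd.DataFrame:
    """Call new samples with a previously fitted model (no re-fitting).

    Adds a ``presence`` column: "0" (absent), ">=1" (at least one copy), or
    "ND" (not determined) for downstream presence/absence tabulation.
    """
    calls = call_copy_numbers(model, new_x_values, new_A_values, threshold)
    presence = []
    for s in calls["S"]:
        if np.isnan(s):
            presence.append("ND")
        elif s == 0:
            presence.append("0")
        else:
            presence.append(">=1")
    calls["presence"] = presence
    return calls
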