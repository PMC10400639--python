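"""Correlation-based inference of cell-ECM-cell communication.

Implements the analysis core: alignment of valid time frames, stationarity-
driven detrending (temporal differencing), Pearson correlation of remodeling
fluctuations, and the three communication readouts -- same-versus-different,
real-versus-fake and matchmaking -- together with temporal-downsampling
sensitivity, leader-follower cross-correlation and pooled nonparametric
statistics.

Correlations are only ever computed between cells of the same experiment
batch; a communicating pair lives in one network/run while the "different"
cell of a triplet comes from another communicating pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .density import DensityTimeSeries

__all__ = [
    "DetrendPolicy",
    "FluctuationSeries",
    "SameVsDifferentResult",
    "MatchmakingResult",
    "longest_valid_mutual_subsequence",
    "stationarity_detrend",
    "pair_correlation",
    "correlate_pair",
    "same_vs_different",
    "place_fake_cell",
    "real_vs_fake",
    "matchmaking",
    "downsample_sensitivity",
    "cross_correlation_leader_follower",
    "pooled_statistics",
]

# minimum usable aligned lengths (frames) by frame interval in minutes
MIN_FRAMES = {15.0: 15, 5.0: 50}
MIN_FRAMES_DOWNSAMPLED = {15.0: 5, 5.0: 15}


class SeriesTooShortError(ValueError):
    pass


class NonStationaryError(ValueError):
    pass


@dataclass
class DetrendPolicy:
    """How to detrend density series before correlating.

    ``fixed_order`` pins the differencing order (2 for simulations, 1 for
    experimental-style series); with ``fixed_order=None`` the order is chosen
    by escalating from 1 until the KPSS test fails to reject stationarity and
    the ADF test rejects non-stationarity, both at ``alpha``.
    """

    fixed_order: int | None = 2
    alpha: float = 0.05
    max_order: int = 2

    @classmethod
    def simulation(cls) -> "DetrendPolicy":
        return cls(fixed_order=2)

    @classmethod
    def experiment(cls) -> "DetrendPolicy":
        return cls(fixed_order=1)

    @classmethod
    def auto(cls) -> "DetrendPolicy":
        return cls(fixed_order=None)


@dataclass
class FluctuationSeries:
    values: np.ndarray
    order: int
    cell_id: str = ""
    pair_id: str = ""
    run_id: str = ""


def longest_valid_mutual_subsequence(
    a: DensityTimeSeries, b: DensityTimeSeries, min_len: int = 0
) -> tuple[np.ndarray, np.ndarray, int]:
    """Longest run of consecutive frames valid in both series.

    Returns the aligned value arrays and the start frame.  Raises
    :class:`SeriesTooShortError` when the longest run is below ``min_len``.
    """
    n = min(len(a), len(b))
    both = a.valid[:n] & b.valid[:n]
    best_start, best_len, start = 0, 0, None
    for i, ok in enumerate(both):
        if ok and start is None:
            start = i
        if (not ok or i == n - 1) and start is not None:
            end = i + 1 if ok else i
            if end - start > best_len:
                best_start, best_len = start, end - start
            start = None
    if best_len < max(min_len, 2):
        raise SeriesTooShortError(
            f"longest mutual valid run is {best_len} < minimum {min_len}"
        )
    sl = slice(best_start, best_start + best_len)
    return a.z[sl], b.z[sl], best_start


def _stationary(values: np.ndarray, alpha: float) -> bool:
    """KPSS fails to reject stationarity AND ADF rejects non-stationarity."""
    from statsmodels.tsa.stattools import adfuller, kpss

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            kpss_p = kpss(values, regression="c", nlags="auto")[1]
            adf_p = adfuller(values, autolag="AIC")[1]
        except (ValueError, np.linalg.LinAlgError):
            return False
    return kpss_p > alpha and adf_p < alpha


def stationarity_detrend(
    values: np.ndarray, policy: DetrendPolicy | None = None, cell_id: str = "",
    pair_id: str = "", run_id: str = "",
) -> FluctuationSeries:
    """Detrend a density series by temporal differencing.

    With a fixed-order policy the stated derivative order is applied directly;
    in auto mode the order escalates (1 then 2) until the series passes the
    stationarity tests, raising :class:`NonStationaryError` if it never does.
    """
    if policy is None:
        policy = DetrendPolicy.simulation()
    values = np.asarray(values, dtype=float)
    if policy.fixed_order is not None:
        out = np.diff(values, n=policy.fixed_order)
        return FluctuationSeries(out, policy.fixed_order, cell_id, pair_id, run_id)
    for order in range(1, policy.max_order + 1):
        out = np.diff(values, n=order)
        if out.size >= 10 and _stationary(out, policy.alpha):
            return FluctuationSeries(out, order, cell_id, pair_id, run_id)
    raise NonStationaryError(
        f"series still non-stationary after order-{policy.max_order} differencing"
    )


def pair_correlation(a, b) -> float:
    """Pearson correlation of two aligned fluctuation series."""
    va = a.values if isinstance(a, FluctuationSeries) else np.asarray(a, float)
    vb = b.values if isinstance(b, FluctuationSeries) else np.asarray(b, float)
    n = min(va.size, vb.size)
    va, vb = va[:n], vb[:n]
    if va.std() == 0.0 or vb.std() == 0.0:
        raise ValueError("zero-variance series: correlation undefined")
    return float(stats.pearsonr(va, vb).statistic)


def correlate_pair(
    a: DensityTimeSeries,
    b: DensityTimeSeries,
    policy: DetrendPolicy | None = None,
    min_len: int = 15,
) -> float:
    """Full correlation path: mutual valid alignment, detrending, Pearson r."""
    za, zb, _ = longest_valid_mutual_subsequence(a, b, min_len=min_len)
    fa = stationarity_detrend(za, policy)
    fb = stationarity_detrend(zb, policy)
    return pair_correlation(fa, fb)


@dataclass
class SameVsDifferentResult:
    same_corrs: np.ndarray  # one per triplet (repeated per matched comparison)
    diff_corrs: np.ndarray
    n_pairs: int
    wilcoxon_stat: float
    wilcoxon_p: float

    @property
    def differences(self) -> np.ndarray:
        return self.same_corrs - self.diff_corrs

    @property
    def fraction_same_higher(self) -> float:
        return float(np.mean(self.differences > 0))

    @property
    def n_triplets(self) -> int:
        return int(self.same_corrs.size)


def same_vs_different(
    pairs: list[tuple[DensityTimeSeries, DensityTimeSeries]],
    policy: DetrendPolicy | None = None,
    min_len: int = 15,
) -> SameVsDifferentResult:
    """Same-versus-different pair analysis over one experiment batch.

    For every ordered triplet (a communicating pair plus one cell from a
    different communicating pair) records the within-pair correlation and the
    cross-pair correlation of the chosen cell with the outside cell.  Reports
    the fraction of triplets with "same" > "different" and a Wilcoxon
    signed-rank test of the paired differences against zero.
    """
    if len(pairs) < 2:
        raise ValueError("same-versus-different requires at least 2 communicating pairs")
    if policy is None:
        policy = DetrendPolicy.simulation()

    same_r = []
    for a, b in pairs:
        try:
            same_r.append(correlate_pair(a, b, policy, min_len))
        except (SeriesTooShortError, ValueError):
            same_r.append(np.nan)

    same_out, diff_out = [], []
    for i, (a, b) in enumerate(pairs):
        if not np.isfinite(same_r[i]):
            continue
        for cell in (a, b):
            for j, (c, d) in enumerate(pairs):
                if j == i:
                    continue
                for other in (c, d):
                    try:
                        r = correlate_pair(cell, other, policy, min_len)
                    except (SeriesTooShortError, ValueError):
                        continue
                    same_out.append(same_r[i])
                    diff_out.append(r)
    same_arr = np.asarray(same_out)
    diff_arr = np.asarray(diff_out)
    stat, p = _signed_rank(same_arr - diff_arr)
    return SameVsDifferentResult(
        same_corrs=same_arr,
        diff_corrs=diff_arr,
        n_pairs=len(pairs),
        wilcoxon_stat=stat,
        wilcoxon_p=p,
    )


def _signed_rank(diffs: np.ndarray) -> tuple[float, float]:
    diffs = diffs[np.isfinite(diffs)]
    if diffs.size < 5:
        return np.nan, np.nan
    nz = diffs[diffs != 0.0]
    if nz.size == 0:
        return np.nan, 1.0  # degenerate: all-zero differences
    res = stats.wilcoxon(nz)
    return float(res.statistic), float(res.pvalue)


def place_fake_cell(
    real_position: np.ndarray,
    pair_distance: float,
    other_positions: np.ndarray,
    n_angles: int = 720,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Place a "fake" partner on the circle of radius ``pair_distance``.

    The point maximizes the minimum distance to all other real cells; with a
    single other cell this lands diametrically opposite it on the circle.  In
    3D the circle lies in the lateral plane through the real cell.  ``bounds``
    (lower, upper corners) restricts candidates to the imaged volume.
    """
    real_position = np.asarray(real_position, dtype=float)
    other = np.atleast_2d(np.asarray(other_positions, dtype=float))
    dim = real_position.shape[0]
    ang = np.arange(n_angles) * (2.0 * np.pi / n_angles)
    ring = np.zeros((n_angles, dim))
    ring[:, 0] = np.cos(ang) * pair_distance
    ring[:, 1] = np.sin(ang) * pair_distance
    cand = real_position[None, :] + ring
    ok = np.ones(n_angles, dtype=bool)
    if bounds is not None:
        lo, hi = bounds
        ok &= np.all((cand >= lo) & (cand <= hi), axis=1)
    if not np.any(ok):
        raise ValueError("no admissible fake-cell location on the placement circle")
    if other.size == 0:
        return cand[np.flatnonzero(ok)[0]]
    dmin = np.min(np.linalg.norm(cand[:, None, :] - other[None, :, :], axis=2), axis=1)
    dmin[~ok] = -np.inf
    return cand[int(np.argmax(dmin))]


def real_vs_fake(
    pairs: list[tuple[DensityTimeSeries, DensityTimeSeries]],
    cell_positions: dict[str, np.ndarray],
    series_source,
    policy: DetrendPolicy | None = None,
    min_len: int = 15,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> SameVsDifferentResult:
    """Real-versus-fake pair analysis.

    For each cell of each communicating pair a fake partner location is solved
    (circle of radius = pair distance, maximal distance to other real cells)
    and quantified through ``series_source(real_cell_id, fake_position)``,
    which must return a :class:`DensityTimeSeries` sampled identically to real
    windows.  Reports the fraction of real-real correlations exceeding the
    matched real-fake correlation.
    """
    if policy is None:
        policy = DetrendPolicy.experiment()
    real_out, fake_out = [], []
    all_ids = list(cell_positions)
    for a, b in pairs:
        try:
            r_real = correlate_pair(a, b, policy, min_len)
        except (SeriesTooShortError, ValueError):
            continue
        dist = np.linalg.norm(cell_positions[a.cell_id] - cell_positions[b.cell_id])
        for cell in (a, b):
            others = np.array(
                [cell_positions[k] for k in all_ids if k != cell.cell_id]
            )
            try:
                fake_pos = place_fake_cell(
                    cell_positions[cell.cell_id], dist, others, bounds=bounds
                )
                fake_series = series_source(cell.cell_id, fake_pos)
                r_fake = correlate_pair(cell, fake_series, policy, min_len)
            except (SeriesTooShortError, ValueError):
                continue
            real_out.append(r_real)
            fake_out.append(r_fake)
    real_arr = np.asarray(real_out)
    fake_arr = np.asarray(fake_out)
    stat, p = _signed_rank(real_arr - fake_arr)
    return SameVsDifferentResult(
        same_corrs=real_arr,
        diff_corrs=fake_arr,
        n_pairs=len(pairs),
        wilcoxon_stat=stat,
        wilcoxon_p=p,
    )


@dataclass
class MatchmakingResult:
    ranks: np.ndarray  # rank of the true partner per evaluated cell, 1..pool size
    pool_size: int
    rng_seed: int | None = None

    @property
    def probability_correct(self) -> float:
        return float(np.mean(self.ranks == 1))


def matchmaking(
    pairs: list[tuple[DensityTimeSeries, DensityTimeSeries]],
    policy: DetrendPolicy | None = None,
    min_len: int = 15,
    n_candidates: int = 49,
    rng_seed: int = 0,
) -> MatchmakingResult:
    """Rank the true communication partner among resampled candidates.

    For every cell, its fluctuation series is correlated with its true partner
    and with ``n_candidates`` candidates sampled with repetition from the other
    cells of the experiment; the partner's position in the descending list of
    correlations is its rank (ties resolved against the partner, i.e. the
    partner takes the worst rank among equal correlations).
    """
    if policy is None:
        policy = DetrendPolicy.experiment()
    rng = np.random.default_rng(rng_seed)
    cells: list[DensityTimeSeries] = []
    partner_of: dict[int, int] = {}
    for a, b in pairs:
        ia, ib = len(cells), len(cells) + 1
        cells.extend([a, b])
        partner_of[ia], partner_of[ib] = ib, ia
    if len(cells) < 4:
        raise ValueError("matchmaking requires at least two pairs")
    ranks = []
    for i, cell in enumerate(cells):
        j = partner_of[i]
        try:
            r_partner = correlate_pair(cell, cells[j], policy, min_len)
        except (SeriesTooShortError, ValueError):
            continue
        candidates = [k for k in range(len(cells)) if k not in (i, j)]
        draw = rng.choice(candidates, size=n_candidates, replace=True)
        r_cand = []
        for k in draw:
            try:
                r_cand.append(correlate_pair(cell, cells[k], policy, min_len))
            except (SeriesTooShortError, ValueError):
                r_cand.append(-np.inf)
        r_cand = np.asarray(r_cand)
        rank = 1 + int(np.sum(r_cand > r_partner)) + int(np.sum(r_cand == r_partner))
        ranks.append(rank)
    return MatchmakingResult(
        ranks=np.asarray(ranks, dtype=int),
        pool_size=n_candidates + 1,
        rng_seed=rng_seed,
    )


def _subsample(series: DensityTimeSeries, factor: int, offset: int) -> DensityTimeSeries:
    sl = slice(offset, None, factor)
    return DensityTimeSeries(
        z=series.z[sl],
        valid=series.valid[sl],
        frame_interval=series.frame_interval * factor,
        cell_id=series.cell_id,
        pair_id=series.pair_id,
        run_id=series.run_id,
        window_distance=series.window_distance,
        offset_perp=series.offset_perp,
    )


def downsample_sensitivity(
    pairs: list[tuple[DensityTimeSeries, DensityTimeSeries]],
    factor: int,
    policy: DetrendPolicy | None = None,
    min_len: int = 5,
) -> SameVsDifferentResult:
    """Same-versus-different at a reduced temporal resolution.

    Every possible starting frame (0..factor-1) defines one subsampled series
    set; the analysis is re-run per offset and the matched comparisons pooled.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return same_vs_different(pairs, policy, min_len)
    same_out, diff_out, n_used = [], [], 0
    for offset in range(factor):
        sub = [(_subsample(a, factor, offset), _subsample(b, factor, offset)) for a, b in pairs]
        try:
            res = same_vs_different(sub, policy, min_len)
        except ValueError:
            continue
        if res.n_triplets == 0:
            continue
        same_out.append(res.same_corrs)
        diff_out.append(res.diff_corrs)
        n_used += 1
    if n_used == 0:
        raise SeriesTooShortError("all subsampled series below the minimum length")
    same_arr = np.concatenate(same_out)
    diff_arr = np.concatenate(diff_out)
    stat, p = _signed_rank(same_arr - diff_arr)
    return SameVsDifferentResult(
        same_corrs=same_arr,
        diff_corrs=diff_arr,
        n_pairs=len(pairs),
        wilcoxon_stat=stat,
        wilcoxon_p=p,
    )


def cross_correlation_leader_follower(
    a: np.ndarray | FluctuationSeries,
    b: np.ndarray | FluctuationSeries,
    max_lag: int = 5,
    min_len: int = 10,
) -> tuple[int | None, float, str | None]:
    """Lagged Pearson cross-correlation between two aligned fluctuation series.

    Correlates a(t) with b(t + lag) for integer lags in [-max_lag, max_lag].
    A positive argmax lag means b trails a, i.e. a leads.  Returns
    ``(lag, r, leader)`` with leader ``"a"``/``"b"`` or ``None`` at lag 0; a
    tie across lags yields ``(None, r, None)``.
    """
    va = a.values if isinstance(a, FluctuationSeries) else np.asarray(a, float)
    vb = b.values if isinstance(b, FluctuationSeries) else np.asarray(b, float)
    n = min(va.size, vb.size)
    va, vb = va[:n], vb[:n]
    lags = np.arange(-max_lag, max_lag + 1)
    rs = np.full(lags.shape, -np.inf)
    for i, lag in enumerate(lags):
        if lag >= 0:
            x, y = va[: n - lag], vb[lag:]
        else:
            x, y = va[-lag:], vb[: n + lag]
        if x.size < min_len or x.std() == 0 or y.std() == 0:
            continue
        rs[i] = stats.pearsonr(x, y).statistic
    best = float(np.max(rs))
    winners = lags[rs >= best - 1e-10]  # numerically exact ties
    if winners.size > 1:
        return None, best, None
    lag = int(winners[0])
    leader = None if lag == 0 else ("a" if lag > 0 else "b")
    return lag, best, leader


def pooled_statistics(
    values: np.ndarray,
    paired: np.ndarray | None = None,
    two_sample: np.ndarray | None = None,
) -> dict:
    """Pooled nonparametric tests.

    One-sample (or paired) Wilcoxon signed-rank against zero, and optionally a
    Wilcoxon rank-sum between ``values`` and ``two_sample``.
    """
    values = np.asarray(values, dtype=float)
    if paired is not None:
        diffs = values - np.asarray(paired, dtype=float)
    else:
        diffs = values
    if diffs.size < 5:
        raise ValueError("need at least 5 observations")
    report: dict = {"n": int(diffs.size)}
    stat, p = _signed_rank(diffs)
    report["signed_rank_stat"] = stat
    report["signed_rank_p"] = p
    if np.all(diffs == 0.0):
        report["degenerate"] = True
    if two_sample is not None:
        res = stats.ranksums(values, np.asarray(two_sample, dtype=float))
        report["rank_sum_stat"] = float(res.statistic)
        report["rank_sum_p"] = float(res.pvalue)
    return report
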