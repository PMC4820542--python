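"""Pupillometry and skin-conductance analysis.

Canonical response functions, signal preprocessing, convolution-GLM design
construction, robust (IRLS bisquare) fitting, outcome-locked epoching with
2x2 median splits, and baseline Bernoulli-variance tuning curves.

The pupillary canonical response function is the gamma-form kernel

    h(t) = t**n * exp(-n * t / t_max)

whose peak is exactly at t_max (defaults n = 10.1, t_max = 930 ms). The
luminance-constriction kernel uses the same family with faster dynamics
(population average n = 3.6, t_max = 839 ms). The skin-conductance kernel is
a gamma density convolved with a Gaussian smoother. All kernels are
peak-normalized to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize, signal, stats

from uncstress._utils import DegenerateInputError, FitError
from uncstress.learning import BeliefTrajectory
from uncstress.task import TaskSchedule

PUPIL_RATE = 100.0  # Hz
SCR_RATE = 10.0  # Hz


@dataclass
class ResponseFunctionParams:
    """Parameters of a canonical response function.

    family 'pupil_gamma' / 'luminance_gamma': h(t) = t^n exp(-n t / t_max).
    family 'scr_gamma_gaussian': gamma(shape, scale) density convolved with a
    Gaussian of sd `smooth_sd_s`.
    """

    family: str = "pupil_gamma"
    n: float = 10.1
    t_max_ms: float = 930.0
    gamma_shape: float = 3.0745
    gamma_scale_s: float = 1.5
    smooth_sd_s: float = 0.3
    rate_hz: float = PUPIL_RATE
    duration_s: float = 4.0

    def validate(self) -> None:
        if self.family not in ("pupil_gamma", "luminance_gamma", "scr_gamma_gaussian"):
            raise ValueError(f"unknown response-function family {self.family!r}")
        if self.family != "scr_gamma_gaussian" and (self.n <= 0 or self.t_max_ms <= 0):
            raise ValueError("n and t_max must be positive")
        if self.family == "scr_gamma_gaussian" and (
            self.gamma_shape <= 0 or self.gamma_scale_s <= 0 or self.smooth_sd_s <= 0
        ):
            raise ValueError("scr kernel parameters must be positive")
        if self.rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("rate and duration must be positive")


def pupil_gamma(t_ms: np.ndarray, n: float, t_max_ms: float) -> np.ndarray:
    """Un-normalized gamma-form pupil kernel; maximum at t = t_max."""
    t = np.asarray(t_ms, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.exp(n * np.log(np.maximum(t, 0.0)) - n * t / t_max_ms)
    h[t <= 0] = 0.0
    return h


def canonical_rf(params: ResponseFunctionParams | None = None) -> np.ndarray:
    """Sample a canonical response function at the modality rate.

    Returns a peak-normalized kernel of length duration_s * rate_hz + 1.
    """
    if params is None:
        params = ResponseFunctionParams()
    params.validate()
    dt = 1.0 / params.rate_hz
    t_s = np.arange(0.0, params.duration_s + dt / 2, dt)
    if params.family in ("pupil_gamma", "luminance_gamma"):
        h = pupil_gamma(t_s * 1000.0, params.n, params.t_max_ms)
    else:
        g = stats.gamma.pdf(t_s, a=params.gamma_shape, scale=params.gamma_scale_s)
        sd_samp = params.smooth_sd_s / dt
        half = int(np.ceil(4 * sd_samp))
        k = np.exp(-0.5 * (np.arange(-half, half + 1) / sd_samp) ** 2)
        h = np.convolve(g, k / k.sum(), mode="full")[: len(t_s)]
    peak = h.max()
    if peak <= 0:
        raise ValueError("kernel is degenerate (non-positive everywhere)")
    return h / peak


def rf_derivatives(kernel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First and second central-difference derivatives, peak-normalized."""
    k = np.asarray(kernel, dtype=float)
    if len(k) < 3:
        raise ValueError("kernel must have at least 3 samples")
    d1 = np.gradient(k)
    d2 = np.gradient(d1)

    def norm(x):
        m = np.abs(x).max()
        return x if m == 0 else x / m

    return norm(d1), norm(d2)


def fit_luminance_rf(
    trace: np.ndarray,
    rate_hz: float = PUPIL_RATE,
    init: tuple[float, float] = (5.0, 800.0),
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((0.5, 40.0), (100.0, 3000.0)),
    n_restarts: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Least-squares fit of (n, t_max_ms) of the gamma family to an
    event-locked average constriction trace (peak-normalized internally).

    An amplitude parameter is profiled out analytically, so only the two
    shape constants are optimized (bounded local search with seeded
    multistart).
    """
    y = np.asarray(trace, dtype=float)
    t_ms = np.arange(len(y)) * 1000.0 / rate_hz
    rng = np.random.default_rng(seed)
    (n_lo, n_hi), (t_lo, t_hi) = bounds

    def sse(x):
        h = pupil_gamma(t_ms, x[0], x[1])
        m = h.max()
        if m <= 0 or not np.isfinite(m):
            return 1e12
        h = h / m
        denom = float(h @ h)
        amp = float(h @ y) / denom if denom > 0 else 0.0
        r = y - amp * h
        return float(r @ r)

    best = None
    starts = [np.array(init)] + [
        np.array([rng.uniform(n_lo, n_hi), rng.uniform(t_lo, t_hi)])
        for _ in range(n_restarts - 1)
    ]
    for x0 in starts:
        res = optimize.minimize(
            sse, x0, method="L-BFGS-B", bounds=[(n_lo, n_hi), (t_lo, t_hi)]
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("luminance response-function fit failed across restarts")
    return float(best.x[0]), float(best.x[1])


# ---------------------------------------------------------------------------
# Time series container and preprocessing
# ---------------------------------------------------------------------------

@dataclass
class PhysioTimeSeries:
    values: np.ndarray
    rate_hz: float
    mask: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))
    blink_intervals_s: list[tuple[float, float]] = field(default_factory=list)
    break_times_s: list[float] = field(default_factory=list)
    zscored: bool = False

    def __post_init__(self):
        if len(self.mask) == 0:
            self.mask = np.zeros(len(self.values), dtype=bool)
        if len(self.mask) != len(self.values):
            raise ValueError("mask length must equal sample length")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.rate_hz


def _downsample(values: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    if rate_in == rate_out:
        return values.copy()
    factor = rate_in / rate_out
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("downsampling requires an integer rate factor")
    return values[:: int(round(factor))]


def preprocess_pupil(raw: PhysioTimeSeries) -> PhysioTimeSeries:
    """Pupil preprocessing chain.

    Downsample to 100 Hz -> zero-phase low-pass (4 Hz, 3rd-order Butterworth)
    -> linear interpolation across blink gaps extended 140 ms either side ->
    linear detrend -> z-score.
    """
    if raw.rate_hz < PUPIL_RATE:
        raise ValueError("raw pupil signal must be sampled at >= 100 Hz")
    if np.std(raw.values) == 0:
        raise DegenerateInputError("pupil signal is constant")
    x = _downsample(np.asarray(raw.values, dtype=float), raw.rate_hz, PUPIL_RATE)
    b, a = signal.butter(3, 4.0 / (PUPIL_RATE / 2.0), btype="low")
    x = signal.filtfilt(b, a, x)

    pad = 0.140
    n = len(x)
    bad = np.zeros(n, dtype=bool)
    for t0, t1 in raw.blink_intervals_s:
        i0 = max(0, int(np.floor((t0 - pad) * PUPIL_RATE)))
        i1 = min(n, int(np.ceil((t1 + pad) * PUPIL_RATE)) + 1)
        bad[i0:i1] = True
    if bad.any():
        good = ~bad
        x[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(good), x[good])

    x = signal.detrend(x, type="linear")
    sd = x.std()
    if sd == 0:
        raise DegenerateInputError("pupil signal is constant after preprocessing")
    x = (x - x.mean()) / sd
    return PhysioTimeSeries(
        values=x,
        rate_hz=PUPIL_RATE,
        blink_intervals_s=list(raw.blink_intervals_s),
        break_times_s=list(raw.break_times_s),
        zscored=True,
    )


def preprocess_scr(
    raw: PhysioTimeSeries,
    schedule: TaskSchedule | None = None,
    mad_threshold: float = 10.0,
    n_trials_after_break: int = 5,
) -> PhysioTimeSeries:
    """Skin-conductance preprocessing chain.

    Low-pass (5 Hz, 1st-order Butterworth, zero-phase, applied at the raw
    rate) -> downsample to 10 Hz -> mask samples whose absolute second
    difference exceeds `mad_threshold` MADs (non-physiological rates of
    change) -> mask the first `n_trials_after_break` trials after each break
    -> linear detrend -> z-score on unmasked samples.
    """
    x = np.asarray(raw.values, dtype=float)
    if raw.rate_hz > SCR_RATE:
        b, a = signal.butter(1, 5.0 / (raw.rate_hz / 2.0), btype="low")
        x = signal.filtfilt(b, a, x)
        x = _downsample(x, raw.rate_hz, SCR_RATE)
    n = len(x)
    mask = np.zeros(n, dtype=bool)

    d2 = np.abs(np.diff(x, 2))
    mad = np.median(np.abs(d2 - np.median(d2)))
    if mad > 0:
        spikes = np.flatnonzero(d2 > mad_threshold * mad) + 1  # centre of the 2nd diff
        for i in spikes:
            mask[max(0, i - 1): min(n, i + 2)] = True

    if schedule is not None and len(schedule.break_after_trial) > 0:
        for brk in schedule.break_after_trial:
            first = brk  # 0-based index of first trial after the break
            last = min(first + n_trials_after_break, schedule.n_trials)
            t0 = schedule.onset_stimulus_ms[first] / 1000.0
            t1 = schedule.trial_end_ms[last - 1] / 1000.0
            i0, i1 = int(t0 * SCR_RATE), min(n, int(np.ceil(t1 * SCR_RATE)) + 1)
            mask[i0:i1] = True

    if mask.mean() > 0.5:
        raise DegenerateInputError(
            f"{mask.mean():.0%} of SCR samples masked; recording quality too low"
        )

    good = ~mask
    x = x - np.polyval(np.polyfit(np.flatnonzero(good), x[good], 1), np.arange(n))
    sd = x[good].std()
    if sd == 0:
        raise DegenerateInputError("SCR signal is constant after preprocessing")
    x = (x - x[good].mean()) / sd
    return PhysioTimeSeries(
        values=x,
        rate_hz=SCR_RATE,
        mask=mask,
        break_times_s=list(raw.break_times_s),
        zscored=True,
    )


# ---------------------------------------------------------------------------
# Convolution GLM
# ---------------------------------------------------------------------------

@dataclass
class PhysioDesign:
    X: np.ndarray
    columns: list[str]
    rate_hz: float
    zscored: bool


def _event_train(times_s, n: int, rate: float, amplitudes=None) -> np.ndarray:
    x = np.zeros(n)
    amps = np.ones(len(times_s)) if amplitudes is None else np.asarray(amplitudes, float)
    for t, a in zip(times_s, amps):
        i = int(round(t * rate))
        if 0 <= i < n:
            x[i] += a
    return x


def _conv(train: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return np.convolve(train, kernel)[: len(train)]


def _orthogonalize(col: np.ndarray, against: np.ndarray) -> np.ndarray:
    denom = float(against @ against)
    if denom == 0:
        return col
    return col - (float(against @ col) / denom) * against


def build_physio_design(
    schedule: TaskSchedule,
    traj: BeliefTrajectory,
    modality: str = "pupil",
    kernel: np.ndarray | None = None,
    luminance_kernel: np.ndarray | None = None,
    n_samples: int | None = None,
    add_derivatives: bool = True,
    add_drift: bool = True,
    standardize: bool = True,
) -> PhysioDesign:
    """Build the convolution design matrix for one subject and modality.

    Event (delta) regressors at stimulus, outcome, shock and rating-prompt
    onsets; a parametric delta at outcome scaled by |delta1|; a boxcar over
    each trial scaled by sigma1hat. All are convolved with the canonical
    kernel. Event regressors optionally get first/second-derivative columns,
    orthogonalized to their primary. Pupil designs add luminance-kernel
    columns at stimulus and outcome onsets. Columns are z-scored after
    convolution when `standardize`; degenerate (constant) columns are
    dropped with a warning.
    """
    if modality not in ("pupil", "scr"):
        raise ValueError(f"unknown modality {modality!r}")
    rate = PUPIL_RATE if modality == "pupil" else SCR_RATE
    if kernel is None:
        fam = "pupil_gamma" if modality == "pupil" else "scr_gamma_gaussian"
        dur = 4.0 if modality == "pupil" else 12.0
        kernel = canonical_rf(
            ResponseFunctionParams(family=fam, rate_hz=rate, duration_s=dur)
        )
    if n_samples is None:
        n_samples = int(np.ceil(schedule.trial_end_ms[-1] / 1000.0 * rate)) + len(kernel)

    stim_t = schedule.onset_stimulus_ms / 1000.0
    out_t = schedule.onset_outcome_ms / 1000.0
    shock_t = out_t[schedule.outcome == 1]
    rating_t = out_t[schedule.is_rating_trial] + 1.0  # prompt follows the outcome

    event_cols: list[tuple[str, np.ndarray]] = [
        ("stimulus", _event_train(stim_t, n_samples, rate)),
        ("outcome", _event_train(out_t, n_samples, rate)),
        ("shock", _event_train(shock_t, n_samples, rate)),
        ("rating", _event_train(rating_t, n_samples, rate)),
        ("surprise", _event_train(out_t, n_samples, rate, np.abs(traj.delta1))),
    ]

    # boxcar over each trial scaled by that trial's irreducible uncertainty
    box = np.zeros(n_samples)
    for k in range(schedule.n_trials):
        i0 = int(round(stim_t[k] * rate))
        i1 = min(n_samples, int(round(schedule.trial_end_ms[k] / 1000.0 * rate)))
        box[i0:i1] = traj.sigma1hat[k]

    cols: list[np.ndarray] = []
    names: list[str] = []
    derivative_of: dict[str, str] = {}
    d1k = d2k = None
    if add_derivatives:
        d1k, d2k = rf_derivatives(kernel)
    for name, train in event_cols:
        if name == "surprise" and np.all(np.abs(traj.delta1) == 0):
            warnings.warn("dropping degenerate design column 'surprise' "
                          "(all prediction errors are zero)")
            continue
        cols.append(_conv(train, kernel))
        names.append(name)
        if add_derivatives and name != "surprise":
            for suffix, dk in (("_d1", d1k), ("_d2", d2k)):
                cols.append(_conv(train, dk))
                names.append(name + suffix)
                derivative_of[name + suffix] = name
    if np.std(traj.sigma1hat) == 0:
        warnings.warn("dropping degenerate design column 'uncertainty' "
                      "(irreducible uncertainty constant across trials)")
    else:
        cols.append(_conv(box, kernel))
        names.append("uncertainty")

    if modality == "pupil":
        if luminance_kernel is None:
            luminance_kernel = canonical_rf(
                ResponseFunctionParams(
                    family="luminance_gamma", n=3.6, t_max_ms=839.0, rate_hz=rate,
                    duration_s=3.0,
                )
            )
        lum_train = _event_train(np.concatenate([stim_t, out_t]), n_samples, rate)
        cols.append(-_conv(lum_train, luminance_kernel))  # constrictions
        names.append("luminance")

    kept, kept_names = [], []
    for c, nm in zip(cols, names):
        sd = c.std()
        if sd == 0:
            warnings.warn(f"dropping degenerate design column {nm!r}")
            continue
        kept.append((c - c.mean()) / sd if standardize else c)
        kept_names.append(nm)
    # orthogonalize derivative columns to their (possibly z-scored) primary,
    # then restore unit scale so the z-scoring invariant is preserved
    for j, nm in enumerate(kept_names):
        prim = derivative_of.get(nm)
        if prim is None or prim not in kept_names:
            continue
        ortho = _orthogonalize(kept[j], kept[kept_names.index(prim)])
        sd = ortho.std()
        kept[j] = ortho / sd if (standardize and sd > 0) else ortho

    if add_drift:
        drift = np.linspace(-1.0, 1.0, n_samples)
        kept.append(drift)
        kept_names.append("drift")
    kept.append(np.ones(n_samples))
    kept_names.append("constant")

    return PhysioDesign(
        X=np.column_stack(kept), columns=kept_names, rate_hz=rate, zscored=standardize
    )


def robust_fit(
    design: PhysioDesign,
    values: np.ndarray,
    mask: np.ndarray | None = None,
    max_iter: int = 50,
):
    """IRLS robust regression (Tukey bisquare, tuning 4.685, MAD scale).

    Masked samples are excluded before fitting. Returns a
    :class:`uncstress.stress.RegressionResult`.
    """
    from uncstress.stress import RegressionResult

    y = np.asarray(values, dtype=float)
    X = design.X
    if mask is not None and np.asarray(mask).any():
        good = ~np.asarray(mask, bool)
        y, X = y[good], X[good]
    n, p = X.shape
    if n <= p:
        raise ValueError("need more unmasked samples than design columns")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685))
        res = model.fit(maxiter=max_iter, scale_est="mad")
    resid = y - X @ res.params
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    resid_var = ss_res / n
    loglik = -0.5 * n * (np.log(2 * np.pi * resid_var) + 1.0) if resid_var > 0 else np.inf
    k = p + 1
    return RegressionResult(
        beta=np.asarray(res.params),
        se=np.asarray(res.bse),
        tvalues=np.asarray(res.tvalues),
        r_squared=max(0.0, r2),
        resid_var=resid_var,
        bic=float(k * np.log(n) - 2 * loglik) if np.isfinite(loglik) else np.nan,
        loglik=float(loglik) if np.isfinite(loglik) else np.nan,
        n=n,
        k=k,
        columns=list(design.columns),
    )


# ---------------------------------------------------------------------------
# Epoching, median splits and tuning curves
# ---------------------------------------------------------------------------

@dataclass
class EpochSet:
    epochs: np.ndarray  # trials x time
    times_s: np.ndarray
    high_uncertainty: np.ndarray  # bool per trial
    high_surprise: np.ndarray
    condition_means: dict  # (unc, surp) -> mean trace


def median_split(x: np.ndarray) -> np.ndarray:
    """Boolean 'high' indicator; ties at the median go to the low bin."""
    x = np.asarray(x, dtype=float)
    return x > np.median(x)


def epoch_median_split(
    series: PhysioTimeSeries,
    schedule: TaskSchedule,
    traj: BeliefTrajectory,
    window_s: tuple[float, float] = (-2.0, 6.0),
) -> EpochSet:
    """Outcome-locked epochs with a 2x2 (uncertainty x surprise) median split."""
    rate = series.rate_hz
    pre, post = window_s
    n_pre = int(round(-pre * rate))
    n_post = int(round(post * rate))
    times = np.arange(-n_pre, n_post + 1) / rate
    n = len(series.values)

    rows = []
    truncated = False
    for k in range(schedule.n_trials):
        c = int(round(schedule.onset_outcome_ms[k] / 1000.0 * rate))
        i0, i1 = c - n_pre, c + n_post + 1
        row = np.full(len(times), np.nan)
        j0, j1 = max(i0, 0), min(i1, n)
        if j1 > j0:
            row[j0 - i0: j1 - i0] = series.values[j0:j1]
        if i0 < 0 or i1 > n:
            truncated = True
        rows.append(row)
    if truncated:
        warnings.warn("epoch window exceeds the record; edge epochs truncated")

    high_u = median_split(traj.sigma1hat)
    high_s = median_split(np.abs(traj.delta1))
    epochs = np.vstack(rows)
    cond_means = {}
    for hu in (False, True):
        for hs in (False, True):
            sel = (high_u == hu) & (high_s == hs)
            cond_means[(hu, hs)] = (
                np.nanmean(epochs[sel], axis=0) if sel.any() else np.full(len(times), np.nan)
            )
    return EpochSet(
        epochs=epochs,
        times_s=times,
        high_uncertainty=high_u,
        high_surprise=high_s,
        condition_means=cond_means,
    )


@dataclass
class TuningResult:
    bin_centers: np.ndarray
    bin_means: np.ndarray
    amplitude: float  # a in a*p*(1-p) + c
    offset: float  # c
    r: float  # Pearson r between fitted curve and bin means


def bernoulli_tuning(values: np.ndarray, beliefs: np.ndarray, n_bins: int = 9) -> TuningResult:
    """Bin per-trial values by belief and fit a*p*(1-p) + c to bin means.

    Equal-width bins over the observed belief range; empty bins are merged
    into their lower neighbour. Returns the Pearson correlation between the
    fitted inverted-U curve and the binned means.
    """
    v = np.asarray(values, dtype=float)
    p = np.asarray(beliefs, dtype=float)
    ok = ~(np.isnan(v) | np.isnan(p))
    v, p = v[ok], p[ok]
    if len(v) < n_bins:
        raise ValueError("fewer trials than bins")
    edges = np.linspace(p.min(), p.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(p, edges) - 1, 0, n_bins - 1)
    centers, means, basis = [], [], []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue  # empty bin merged by omission
        centers.append(p[sel].mean())
        means.append(v[sel].mean())
        # within-bin mean of p(1-p): the Bernoulli-variance predictor
        # aggregated the same way as the response
        basis.append((p[sel] * (1.0 - p[sel])).mean())
    centers = np.asarray(centers)
    means = np.asarray(means)
    basis = np.asarray(basis)
    A = np.column_stack([basis, np.ones_like(basis)])
    (a, c), *_ = np.linalg.lstsq(A, means, rcond=None)
    fitted = a * basis + c
    if np.std(fitted) == 0 or np.std(means) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(fitted, means)[0, 1])
    return TuningResult(
        bin_centers=centers, bin_means=means, amplitude=float(a), offset=float(c), r=r
    )


def baseline_tuning(
    series: PhysioTimeSeries,
    schedule: TaskSchedule,
    traj: BeliefTrajectory,
    n_bins: int = 9,
    baseline_window_s: float = 0.5,
) -> TuningResult:
    """Inverted-U tuning of pre-stimulus baseline arousal with belief.

    Baseline is the mean signal over the `baseline_window_s` preceding each
    stimulus onset.
    """
    rate = series.rate_hz
    w = int(round(baseline_window_s * rate))
    baselines = np.full(schedule.n_trials, np.nan)
    for k in range(schedule.n_trials):
        i1 = int(round(schedule.onset_stimulus_ms[k] / 1000.0 * rate))
        i0 = max(0, i1 - w)
        if i1 > i0:
            seg = series.values[i0:i1]
            if len(series.mask) == len(series.values):
                good = ~series.mask[i0:i1]
                seg = seg[good] if good.any() else seg[:0]
            if len(seg):
                baselines[k] = seg.mean()
    return bernoulli_tuning(baselines, traj.mu1hat, n_bins=n_bins)
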