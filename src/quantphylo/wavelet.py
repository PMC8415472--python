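"""Bivariate Morlet wavelet analysis of number strings.

Two number strings are compared in the position–period plane: the continuous
Morlet wavelet transform of each (position treated as a spatial series with
unit spacing), their cross-spectrum W_xy = W_x · conj(W_y), the cross-wavelet
power |W_xy| (a covariance analogue), the squared wavelet coherence
|S(W_xy)|² / (S(|W_x|²)·S(|W_y|²)) in [0, 1] (a correlation analogue,
where S smooths over position with a scale-proportional window and over
scale with a fixed-octave window), and the phase difference arg(W_xy) in
(−π, π] — in-phase when it lies in (−π/2, π/2), out-of-phase otherwise.

Significance is assessed by Monte-Carlo surrogates: pairs of white-noise
series matched to the inputs' lengths, means and variances.  A cell of the
coherence map is locally significant when the observed coherence exceeds the
(1 − α) surrogate quantile for that cell; a period's average cross power is
significant analogously.  All stochastic steps take an explicit seed.

The Morlet mother wavelet uses central angular frequency ω₀ = 6, for which
the Fourier period is ≈ 1.033 × scale.  Scales form a dyadic grid between
the requested shortest and longest Fourier periods.  Estimates inside the
cone of influence (edge regions where zero padding leaks in) are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np

__all__ = [
    "WaveletParams",
    "CrossWaveletResult",
    "fourier_factor",
    "morlet_cwt",
    "cross_wavelet",
    "wavelet_coherence",
    "significance",
    "analyze_pair",
    "phase_classification",
    "render_plots",
    "matrix_to_tsv",
    "matrix_from_tsv",
]


@dataclass(frozen=True)
class WaveletParams:
    """Tunable parameters of the bivariate wavelet analysis.

    ``omega0`` is the Morlet central angular frequency; ``period_min`` /
    ``period_max`` bound the dyadic grid of Fourier periods (in alignment
    positions); ``suboctaves`` is the number of voices per octave;
    ``n_surrogates`` the Monte-Carlo sample size; ``sig_level_local`` the
    significance level for per-cell (joint-period contour) tests and
    ``sig_level_avg`` the level for the average-power-per-period test;
    ``surrogate_model`` is ``"white"`` (default) or ``"ar1"``.
    """

    omega0: float = 6.0
    period_min: float = 2.0
    period_max: float = 256.0
    suboctaves: int = 20
    n_surrogates: int = 100
    sig_level_local: float = 0.05
    sig_level_avg: float = 0.1
    rng_seed: int = 1
    surrogate_model: str = "white"

    def __post_init__(self) -> None:
        if not self.period_min < self.period_max:
            raise ValueError("period_min must be < period_max")
        for lvl in (self.sig_level_local, self.sig_level_avg):
            if not 0.0 < lvl < 1.0:
                raise ValueError("significance levels must lie in (0, 1)")
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        if self.surrogate_model not in ("white", "ar1"):
            raise ValueError("surrogate_model must be 'white' or 'ar1'")


@dataclass
class CrossWaveletResult:
    """All derived fields of a bivariate analysis on a period × position grid."""

    positions: np.ndarray  # 1..L
    periods: np.ndarray  # Fourier periods, one per scale
    cross_power: np.ndarray | None = None  # |W_xy|
    phase: np.ndarray | None = None  # arg(W_xy) in (−π, π]
    coherence: np.ndarray | None = None  # squared coherence in [0, 1]
    sig_local: np.ndarray | None = None  # per-cell significance (coherence)
    avg_power: np.ndarray | None = None  # per-period mean cross power
    avg_sig: np.ndarray | None = None  # per-period significance
    cone_of_influence: np.ndarray | None = None  # per-position max valid period

    def in_cone(self) -> np.ndarray:
        """Boolean mask of cells inside the cone of influence (trustworthy)."""
        return self.periods[:, None] <= self.cone_of_influence[None, :]


def fourier_factor(omega0: float = 6.0) -> float:
    """Ratio of Fourier period to Morlet scale: 4π / (ω₀ + √(2 + ω₀²))."""
    return 4.0 * np.pi / (omega0 + np.sqrt(2.0 + omega0**2))


def _scales(params: WaveletParams, n: int) -> Tuple[np.ndarray, np.ndarray]:
    ff = fourier_factor(params.omega0)
    period_max = params.period_max
    if period_max > n:
        warnings.warn(
            f"period_max {period_max} exceeds signal length {n}; clipping"
        )
        period_max = float(n)
    dj = 1.0 / params.suboctaves
    s0 = params.period_min / ff
    n_oct = np.log2(period_max / params.period_min)
    j = np.arange(0, np.floor(n_oct / dj) + 1)
    scales = s0 * 2.0 ** (j * dj)
    return scales, scales * ff


def morlet_cwt(
    x, params: WaveletParams = WaveletParams()
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Continuous Morlet transform of one series.

    The series is mean-centered, zero-padded to the next power of two and
    transformed in the frequency domain at each scale of the dyadic grid.
    Returns ``(W, periods, coi)``: complex coefficients (scales × positions),
    the Fourier period of each scale, and the cone of influence as the
    largest trustworthy period per position.
    """
    xv = np.asarray(x, dtype=float)
    n = len(xv)
    if n < 4:
        raise ValueError("need at least 4 positions")
    scales, periods = _scales(params, n)
    xc = xv - xv.mean()
    npad = int(2 ** np.ceil(np.log2(n)))
    fx = np.fft.fft(xc, npad)
    omega = 2.0 * np.pi * np.fft.fftfreq(npad)  # angular frequency, dt = 1
    W = np.empty((len(scales), n), dtype=complex)
    norm_const = np.pi**-0.25
    for k, s in enumerate(scales):
        # Morlet daughter in frequency space, admissible (ω > 0) part only
        psi = np.zeros(npad)
        pos = omega > 0
        psi[pos] = (
            np.sqrt(2.0 * np.pi * s)
            * norm_const
            * np.exp(-((s * omega[pos] - params.omega0) ** 2) / 2.0)
        )
        W[k] = np.fft.ifft(fx * psi)[:n]
    ff = fourier_factor(params.omega0)
    t = np.arange(n, dtype=float)
    coi = ff * np.sqrt(2.0) * np.minimum(t + 0.5, n - t - 0.5)
    return W, periods, coi


def _smooth(
    M: np.ndarray, scales: np.ndarray, params: WaveletParams
) -> np.ndarray:
    """Coherence smoothing: boxcar over position with width ∝ scale,
    then boxcar over scale spanning 0.6 octave."""
    out = np.empty_like(M, dtype=float)
    n = M.shape[1]
    for k, s in enumerate(scales):
        w = max(3, int(round(2.0 * s)) | 1)  # odd window, ≥ 3
        w = min(w, (n - 1) | 1)  # convolve 'same' needs kernel ≤ signal
        kern = np.ones(w) / w
        out[k] = np.convolve(M[k], kern, mode="same")
    # scale smoothing: 0.6 octave = 0.6 * suboctaves voices
    sw = max(1, int(round(0.6 * params.suboctaves)) | 1)
    sw = min(sw, (M.shape[0] - 1) | 1)
    kern = np.ones(sw) / sw
    for j in range(out.shape[1]):
        out[:, j] = np.convolve(out[:, j], kern, mode="same")
    return out


def cross_wavelet(
    x, y, params: WaveletParams = WaveletParams()
) -> CrossWaveletResult:
    """Cross-spectrum of two equal-length series: power and phase fields."""
    xv, yv = np.asarray(x, float), np.asarray(y, float)
    if xv.shape != yv.shape:
        raise ValueError(f"length mismatch: {len(xv)} vs {len(yv)}")
    Wx, periods, coi = morlet_cwt(xv, params)
    Wy, _, _ = morlet_cwt(yv, params)
    Wxy = Wx * np.conj(Wy)
    res = CrossWaveletResult(
        positions=np.arange(1, len(xv) + 1),
        periods=periods,
        cross_power=np.abs(Wxy),
        phase=np.angle(Wxy),
        cone_of_influence=coi,
    )
    res.avg_power = res.cross_power.mean(axis=1)
    return res


def _coherence_from_transforms(
    Wx: np.ndarray, Wy: np.ndarray, scales: np.ndarray, params: WaveletParams
) -> np.ndarray:
    # 1/s weighting before smoothing, per standard cross-wavelet practice
    inv_s = (1.0 / scales)[:, None]
    Sxy_re = _smooth((Wx * np.conj(Wy)).real * inv_s, scales, params)
    Sxy_im = _smooth((Wx * np.conj(Wy)).imag * inv_s, scales, params)
    Sxx = _smooth(np.abs(Wx) ** 2 * inv_s, scales, params)
    Syy = _smooth(np.abs(Wy) ** 2 * inv_s, scales, params)
    denom = Sxx * Syy
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = (Sxy_re**2 + Sxy_im**2) / denom
    coh = np.nan_to_num(coh, nan=0.0)
    return np.clip(coh, 0.0, 1.0)


def wavelet_coherence(
    x, y, params: WaveletParams = WaveletParams()
) -> CrossWaveletResult:
    """Squared wavelet coherence of two series, with power and phase."""
    xv, yv = np.asarray(x, float), np.asarray(y, float)
    if xv.shape != yv.shape:
        raise ValueError(f"length mismatch: {len(xv)} vs {len(yv)}")
    Wx, periods, coi = morlet_cwt(xv, params)
    Wy, _, _ = morlet_cwt(yv, params)
    scales = periods / fourier_factor(params.omega0)
    Wxy = Wx * np.conj(Wy)
    res = CrossWaveletResult(
        positions=np.arange(1, len(xv) + 1),
        periods=periods,
        cross_power=np.abs(Wxy),
        phase=np.angle(Wxy),
        coherence=_coherence_from_transforms(Wx, Wy, scales, params),
        cone_of_influence=coi,
    )
    res.avg_power = res.cross_power.mean(axis=1)
    return res


def _surrogate_stats(
    n: int,
    moments: Tuple[float, float, float, float],
    params: WaveletParams,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Coherence map and per-period average cross power of one white-noise
    surrogate pair matched to the originals' means and variances."""
    mx, sx, my, sy = moments
    xs = rng.normal(mx, sx, n)
    ys = rng.normal(my, sy, n)
    Wx, periods, _ = morlet_cwt(xs, params)
    Wy, _, _ = morlet_cwt(ys, params)
    scales = periods / fourier_factor(params.omega0)
    coh = _coherence_from_transforms(Wx, Wy, scales, params)
    avg = np.abs(Wx * np.conj(Wy)).mean(axis=1)
    return coh, avg


def significance(
    x, y, params: WaveletParams = WaveletParams()
) -> CrossWaveletResult:
    """Full bivariate analysis with Monte-Carlo significance masks.

    ``sig_local`` flags coherence cells exceeding the per-cell
    (1 − sig_level_local) quantile of white-noise surrogates; ``avg_sig``
    flags periods whose average cross power exceeds the per-period
    (1 − sig_level_avg) surrogate quantile.
    """
    if params.n_surrogates < 20:
        warnings.warn(
            f"{params.n_surrogates} surrogates give coarse quantiles; "
            "consider >= 20"
        )
    xv, yv = np.asarray(x, float), np.asarray(y, float)
    res = wavelet_coherence(xv, yv, params)
    rng = np.random.default_rng(params.rng_seed)
    n = len(xv)
    moments = (
        float(xv.mean()),
        float(xv.std()) or 1.0,
        float(yv.mean()),
        float(yv.std()) or 1.0,
    )
    coh_stack = np.empty((params.n_surrogates,) + res.coherence.shape)
    avg_stack = np.empty((params.n_surrogates, len(res.periods)))
    for b in range(params.n_surrogates):
        if params.surrogate_model == "white":
            coh_b, avg_b = _surrogate_stats(n, moments, params, rng)
        else:
            xs = _ar1_surrogate(xv, rng)
            ys = _ar1_surrogate(yv, rng)
            Wx, periods, _ = morlet_cwt(xs, params)
            Wy, _, _ = morlet_cwt(ys, params)
            scales = periods / fourier_factor(params.omega0)
            coh_b = _coherence_from_transforms(Wx, Wy, scales, params)
            avg_b = np.abs(Wx * np.conj(Wy)).mean(axis=1)
        coh_stack[b] = coh_b
        avg_stack[b] = avg_b
    q_local = np.quantile(coh_stack, 1.0 - params.sig_level_local, axis=0)
    q_avg = np.quantile(avg_stack, 1.0 - params.sig_level_avg, axis=0)
    res.sig_local = res.coherence > q_local
    res.avg_sig = res.avg_power > q_avg
    return res


def _ar1_surrogate(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """AR(1) surrogate matched to the series' mean, variance and lag-1
    autocorrelation."""
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    phi = float(np.dot(xc[:-1], xc[1:])) / denom if denom > 0 else 0.0
    phi = np.clip(phi, -0.99, 0.99)
    innov_sd = x.std() * np.sqrt(max(1.0 - phi**2, 1e-12))
    out = np.empty(len(x))
    out[0] = rng.normal(0.0, x.std() or 1.0)
    eps = rng.normal(0.0, innov_sd or 1.0, len(x) - 1)
    for t in range(1, len(x)):
        out[t] = phi * out[t - 1] + eps[t - 1]
    return out + x.mean()


analyze_pair = significance  # full pipeline alias


def phase_classification(phase: float) -> str:
    """Classify a phase angle: in-phase on (−π/2, π/2), out-of-phase on
    (π/2, π) ∪ (−π, −π/2); the boundary angles ±π/2 and π count as
    out-of-phase."""
    if not -np.pi < phase <= np.pi + 1e-12:
        raise ValueError(f"phase {phase} outside (−π, π]")
    return "in_phase" if -np.pi / 2 < phase < np.pi / 2 else "out_of_phase"


def matrix_to_tsv(res_field: np.ndarray, periods: np.ndarray, positions: np.ndarray) -> str:
    lines = ["period\\position\t" + "\t".join(str(int(p)) for p in positions)]
    for per, row in zip(periods, res_field):
        lines.append(repr(float(per)) + "\t" + "\t".join(repr(float(v)) for v in row))
    return "\n".join(lines) + "\n"


def matrix_from_tsv(text: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    positions = np.array([float(v) for v in lines[0].split("\t")[1:]])
    periods, rows = [], []
    for ln in lines[1:]:
        parts = ln.split("\t")
        periods.append(float(parts[0]))
        rows.append([float(v) for v in parts[1:]])
    return np.array(rows), np.array(periods), positions


def render_plots(res: CrossWaveletResult, out_dir) -> Dict[str, str]:
    """Write the four standard figures and TSV matrices to ``out_dir``.

    (A) average cross power per period with significance dots; (B) phase
    image with in-phase and out-of-phase bands in distinct colormaps;
    (C) coherence heat map with significance contours and phase arrows in
    significant regions; (D) cross-power heat map with phase arrows.
    Returns a name → path map of everything written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: Dict[str, str] = {}

    P, X = np.meshgrid(res.positions, res.periods)

    # (A) average power vs period
    fig, ax = plt.subplots(figsize=(4, 5))
    ax.plot(res.avg_power, res.periods, color="black", lw=1)
    if res.avg_sig is not None and res.avg_sig.any():
        ax.plot(
            res.avg_power[res.avg_sig],
            res.periods[res.avg_sig],
            "o", color="red", ms=4,
        )
    ax.set_yscale("log", base=2)
    ax.invert_yaxis()
    ax.set_xlabel("average cross-wavelet power")
    ax.set_ylabel("Fourier period")
    fig.tight_layout()
    p = out / "average_power.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written["average_power"] = str(p)

    # (B) phase image: in-phase greens/yellows vs out-of-phase blues/reds
    fig, ax = plt.subplots(figsize=(7, 4))
    in_phase = (res.phase > -np.pi / 2) & (res.phase < np.pi / 2)
    shade = np.where(in_phase, res.phase, np.nan)
    m = ax.pcolormesh(P, X, shade, cmap="summer", vmin=-np.pi / 2, vmax=np.pi / 2)
    shade_out = np.where(~in_phase, res.phase, np.nan)
    ax.pcolormesh(P, X, shade_out, cmap="coolwarm", vmin=-np.pi, vmax=np.pi)
    ax.set_yscale("log", base=2)
    ax.invert_yaxis()
    ax.set_xlabel("position")
    ax.set_ylabel("Fourier period")
    fig.colorbar(m, ax=ax, label="phase (in-phase band)")
    fig.tight_layout()
    p = out / "phase_difference.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written["phase_difference"] = str(p)

    def _arrows(ax, mask):
        if mask is None:
            return
        step_x = max(1, len(res.positions) // 30)
        step_p = max(1, len(res.periods) // 15)
        for i in range(0, len(res.periods), step_p):
            for j in range(0, len(res.positions), step_x):
                if mask[i, j]:
                    ang = res.phase[i, j]
                    ax.annotate(
                        "",
                        xy=(res.positions[j] + 3 * np.cos(ang),
                            res.periods[i] * 2 ** (0.1 * np.sin(ang))),
                        xytext=(res.positions[j], res.periods[i]),
                        arrowprops=dict(arrowstyle="->", lw=0.6, color="black"),
                    )

    # (C) coherence
    if res.coherence is not None:
        fig, ax = plt.subplots(figsize=(7, 4))
        m = ax.pcolormesh(P, X, res.coherence, cmap="jet", vmin=0, vmax=1)
        if res.sig_local is not None:
            ax.contour(P, X, res.sig_local.astype(float), levels=[0.5],
                       colors="white", linewidths=1)
            _arrows(ax, res.sig_local)
        ax.plot(res.positions, res.cone_of_influence, "k--", lw=0.8)
        ax.set_yscale("log", base=2)
        ax.set_ylim(res.periods.max(), res.periods.min())
        ax.set_xlabel("position")
        ax.set_ylabel("Fourier period")
        fig.colorbar(m, ax=ax, label="coherence")
        fig.tight_layout()
        p = out / "coherence.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written["coherence"] = str(p)

    # (D) cross power
    fig, ax = plt.subplots(figsize=(7, 4))
    m = ax.pcolormesh(P, X, res.cross_power, cmap="jet")
    _arrows(ax, res.sig_local)
    ax.plot(res.positions, res.cone_of_influence, "k--", lw=0.8)
    ax.set_yscale("log", base=2)
    ax.set_ylim(res.periods.max(), res.periods.min())
    ax.set_xlabel("position")
    ax.set_ylabel("Fourier period")
    fig.colorbar(m, ax=ax, label="cross-wavelet power")
    fig.tight_layout()
    p = out / "cross_power.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written["cross_power"] = str(p)

    fields = {
        "cross_power": res.cross_power,
        "phase": res.phase,
        "coherence": res.coherence,
        "sig_local": None if res.sig_local is None else res.sig_local.astype(float),
    }
    for name, mat in fields.items():
        if mat is None:
            continue
        p = out / f"{name}.tsv"
        p.write_text(matrix_to_tsv(mat, res.periods, res.positions))
        written[f"{name}_tsv"] = str(p)
    return written
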