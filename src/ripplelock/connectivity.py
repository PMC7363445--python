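"""Cross-regional connectivity between neocortex and hippocampus.

All measures operate on trial ensembles of complex Morlet coefficients
(:class:`~ripplelock.spectral.TFRStack`), keeping every analysis in the same
wavelet framework:

* coherence — trial-ensemble magnitude coherence per (frequency, time);
* PLV — phase-locking value, the magnitude of the trial-averaged unit
  phasor of the inter-channel phase difference;
* orthogonalized power correlation — amplitude coupling computed after
  removing the instantaneously in-phase component, immune to volume
  conduction and common-reference artifacts;
* PDC — non-parametric partial directed coherence: trial-averaged
  cross-spectral matrices on sliding 512 ms windows are factorized with
  Wilson's spectral matrix factorization into a transfer function H(f) and
  noise covariance, and the PDC is formed from Ā(f) = H(f)⁻¹ with
  column-wise (outflow) normalisation.  No autoregressive model is fitted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .spectral import TFRStack

logger = logging.getLogger(__name__)


def _nanmean(a, axis=None):
    """np.nanmean that stays quiet on all-NaN (edge) cells."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(a, axis=axis)



# ---------------------------------------------------------------------------
# ensemble measures on TFR stacks


def _aligned(tfr_x: np.ndarray, tfr_y: np.ndarray) -> None:
    if tfr_x.shape != tfr_y.shape:
        raise ValueError("channel stacks must have identical shape")


def coherence(tfr_x: np.ndarray, tfr_y: np.ndarray,
              squared: bool = False) -> np.ndarray:
    """Trial-ensemble (magnitude) coherence per (frequency, time).

    ``tfr_x``/``tfr_y`` are complex (n_trials, n_freqs, n_times) arrays of
    one channel each.  Returns values in [0, 1]; NaN where edge cells are
    invalid.
    """
    _aligned(tfr_x, tfr_y)
    if tfr_x.shape[0] < 2:
        raise ValueError("coherence is degenerate with a single trial")
    sxy = _nanmean(tfr_x * np.conj(tfr_y), axis=0)
    sxx = _nanmean(np.abs(tfr_x) ** 2, axis=0)
    syy = _nanmean(np.abs(tfr_y) ** 2, axis=0)
    denom = np.sqrt(sxx * syy)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(sxy) / denom
    if squared:
        coh = coh ** 2
    return coh


def plv(tfr_x: np.ndarray, tfr_y: np.ndarray) -> np.ndarray:
    """Phase-locking value per (frequency, time), in [0, 1]."""
    _aligned(tfr_x, tfr_y)
    if tfr_x.shape[0] < 2:
        raise ValueError("PLV needs at least two trials")
    with np.errstate(invalid="ignore", divide="ignore"):
        phasor = (tfr_x * np.conj(tfr_y))
        phasor = phasor / np.abs(phasor)
    return np.abs(_nanmean(phasor, axis=0))


def orthogonalized_power_correlation(tfr_x: np.ndarray, tfr_y: np.ndarray,
                                     min_residual_frac: float = 1e-12
                                     ) -> np.ndarray:
    """Orthogonalized power correlation per (frequency, time), in [-1, 1].

    Per cell, Y is orthogonalized with respect to X (keeping only the
    instantaneously out-of-phase component, ``imag(Y·conj(X)/|X|)``), the
    trial-wise correlation between power(X) and power(Y⊥X) is computed, the
    symmetric X⊥Y counterpart likewise, and the two maps averaged.  Cells
    where the residual power vanishes (collinear signals) are NaN.
    """
    _aligned(tfr_x, tfr_y)
    if tfr_x.shape[0] < 3:
        raise ValueError("power correlation needs at least three trials")

    def _one_direction(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        # b orthogonalized w.r.t. a, correlated with power of a
        with np.errstate(invalid="ignore", divide="ignore"):
            b_orth = np.imag(b * np.conj(a) / np.abs(a))
        pa = np.abs(a) ** 2
        pb = b_orth ** 2
        resid_frac = _nanmean(pb, axis=0) / np.maximum(
            _nanmean(np.abs(b) ** 2, axis=0), 1e-300)
        corr = _pearson_over_trials(pa, pb)
        corr[resid_frac < min_residual_frac] = np.nan
        return corr

    return 0.5 * (_one_direction(tfr_x, tfr_y) + _one_direction(tfr_y, tfr_x))


def _pearson_over_trials(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    am = a - np.nanmean(a, axis=0)
    bm = b - np.nanmean(b, axis=0)
    num = np.nansum(am * bm, axis=0)
    den = np.sqrt(np.nansum(am**2, axis=0) * np.nansum(bm**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def band_mean(metric: np.ndarray, freqs: np.ndarray,
              band: tuple[float, float] = (12.0, 16.0)) -> np.ndarray:
    """Frequency-mean of a (freq, time) map within a band -> time series."""
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValueError(f"band {band} outside the frequency grid")
    return _nanmean(metric[sel], axis=0)


# alias matching the analysis vocabulary
band_coherence_timecourse = band_mean


def window_mean(metric: np.ndarray, freqs: np.ndarray, times: np.ndarray,
                t_window: tuple[float, float] = (-0.22, 0.46),
                f_window: tuple[float, float] = (11.5, 18.0)) -> float:
    """Mean of a (freq, time) map over a time × frequency rectangle."""
    fsel = (freqs >= f_window[0]) & (freqs <= f_window[1])
    tsel = (times >= t_window[0]) & (times <= t_window[1])
    if not fsel.any() or not tsel.any():
        raise ValueError("empty window selection")
    return float(_nanmean(metric[np.ix_(fsel, tsel)]))


# ---------------------------------------------------------------------------
# Wilson spectral matrix factorization and non-parametric PDC


def wilson_factorize(S: np.ndarray, tol: float = 1e-9, max_iter: int = 200
                     ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Factorize a one-sided cross-spectral density S(f) = H(f) Σ H(f)ᴴ.

    Parameters
    ----------
    S : complex (n_freqs, n_ch, n_ch)
        Hermitian PSD matrices on a uniform frequency grid from 0 to the
        band's Nyquist-equivalent edge (inclusive).

    Returns
    -------
    H : complex (n_freqs, n_ch, n_ch) minimum-phase transfer function
    Sigma : (n_ch, n_ch) real innovation covariance
    converged : bool

    Implements Wilson's iteration: the two-sided spectrum is built by
    Hermitian reflection, ψ is refined by ψ ← ψ·[ψ⁻¹ S ψ⁻ᴴ + I]₊ where
    [·]₊ keeps the causal part, and H = ψ A₀⁻¹, Σ = A₀A₀ᴴ with A₀ the
    zero-lag coefficient.
    """
    nf, nc, _ = S.shape
    n = 2 * (nf - 1)
    # the DC and Nyquist-edge matrices of a real process are real; CSDs
    # estimated on a partial band (wavelet grids) need this enforced or no
    # consistent real-lag spectrum exists and the iteration stalls
    S = S.copy()
    S[0] = S[0].real
    S[-1] = S[-1].real
    # two-sided spectrum on the frequency circle
    Sfull = np.empty((n, nc, nc), complex)
    Sfull[:nf] = S
    # S(-f) = conj(S(f)) elementwise for real processes (equivalently the
    # transpose, given Hermitian S)
    Sfull[nf:] = np.conj(S[-2:0:-1])

    # initial ψ: Cholesky of the spectral mean, constant over frequency
    S_mean = Sfull.mean(axis=0)
    S_mean = (S_mean + S_mean.conj().T) / 2
    try:
        # upper-triangular Cholesky factor, matching the upper-triangular
        # zero-lag condition in the plus operator
        psi0 = np.linalg.cholesky(S_mean + 1e-12 * np.trace(S_mean).real
                                  / nc * np.eye(nc)).conj().T
    except np.linalg.LinAlgError:
        psi0 = np.eye(nc) * np.sqrt(np.trace(S_mean).real / nc)
    psi = np.broadcast_to(psi0, (n, nc, nc)).astype(complex).copy()

    eye = np.eye(nc)
    converged = False
    best_err = np.inf
    stall = 0
    for _ in range(max_iter):
        psi_inv = np.linalg.inv(psi)
        g = psi_inv @ Sfull @ np.conj(psi_inv).transpose(0, 2, 1)
        gp = _plus_operator(g + eye[None])
        psi_new = psi @ gp
        err = np.max(np.abs(psi_new - psi)) / max(np.max(np.abs(psi)), 1e-300)
        psi = psi_new
        if err < tol:
            converged = True
            break
        # smoothed spectra can limit-cycle at a small residual; stop once
        # the step size no longer improves
        if err < 0.995 * best_err:
            best_err = err
            stall = 0
        else:
            stall += 1
            if stall >= 15:
                break

    # zero-lag coefficient
    A0 = np.real(np.fft.ifft(psi, axis=0)[0])
    try:
        A0_inv = np.linalg.inv(A0)
    except np.linalg.LinAlgError:
        return psi[:nf], A0 @ A0.T, False
    H = psi[:nf] @ A0_inv
    Sigma = A0 @ A0.T
    return H, Sigma, converged


def _plus_operator(g: np.ndarray) -> np.ndarray:
    """Causal part of a spectral matrix function on the frequency circle.

    Lags are real for a Hermitian spectrum; negative lags are zeroed and
    the zero-lag term is halved with its strictly lower triangle removed —
    the triangularity condition that makes the Wilson factor unique
    (fixing the otherwise arbitrary unitary rotation).
    """
    n = g.shape[0]
    nf = n // 2 + 1
    gam = np.fft.ifft(g, axis=0).real
    gam[0] = np.triu(0.5 * gam[0])
    gam[nf:] = 0
    return np.fft.fft(gam, axis=0)


def pdc_from_csd(S: np.ndarray, tol: float = 1e-9, max_iter: int = 200,
                 max_recon_err: float = 0.05,
                 generalized: bool = False) -> tuple[np.ndarray, bool]:
    """Partial directed coherence from a one-sided CSD.

    Returns (pi, ok) with ``pi[f, i, j]`` = influence j -> i,
    column-normalised so that Σ_i |π_{i←j}|² = 1 per source j and
    frequency (the original outflow form); with ``generalized=True`` the
    entries are weighted by the inverse innovation SDs before
    normalisation, which removes scale differences between channels.
    ``ok`` is True when the factorization either converged to ``tol`` or
    reconstructs the spectrum to within ``max_recon_err`` median relative
    Frobenius error — smoothed (wavelet) spectra often settle at a
    fraction of a percent without meeting a strict step-size criterion,
    which is ample for PDC.
    """
    H, Sigma, converged = wilson_factorize(S, tol=tol, max_iter=max_iter)
    ok = converged
    if not ok:
        S_chk = S.copy()
        S_chk[0] = S_chk[0].real
        S_chk[-1] = S_chk[-1].real
        recon = H @ Sigma @ np.conj(H).transpose(0, 2, 1)
        num = np.linalg.norm(recon - S_chk, axis=(1, 2))
        den = np.maximum(np.linalg.norm(S_chk, axis=(1, 2)), 1e-300)
        ok = bool(np.median(num / den) < max_recon_err)
    Abar = np.linalg.inv(H)
    W = np.abs(Abar)
    if generalized:
        inv_sd = 1.0 / np.sqrt(np.maximum(np.diag(Sigma).real, 1e-300))
        W = W * inv_sd[None, :, None]
    denom = np.sqrt(np.sum(W ** 2, axis=1, keepdims=True))
    pi = W / np.maximum(denom, 1e-300)
    return pi, ok


def analytic_var_pdc(coeffs: list[np.ndarray] | np.ndarray,
                     freqs: np.ndarray, fs: float) -> np.ndarray:
    """Closed-form PDC of a known VAR process (oracle for validation).

    ``coeffs`` is the list of lag matrices A_1..A_p; the PDC is formed from
    Ā(f) = I − Σ_k A_k e^{−i2πfk/fs} with the same column normalisation as
    :func:`pdc_from_csd`.
    """
    coeffs = np.asarray(coeffs)
    p, nc, _ = coeffs.shape
    out = np.empty((len(freqs), nc, nc))
    for fi, f in enumerate(freqs):
        A = np.eye(nc, dtype=complex)
        for k in range(p):
            A = A - coeffs[k] * np.exp(-2j * np.pi * f * (k + 1) / fs)
        denom = np.sqrt(np.sum(np.abs(A) ** 2, axis=0, keepdims=True))
        out[fi] = np.abs(A) / denom
    return out


@dataclass
class PDCResult:
    """Time-resolved PDC between the two channels of an epoch ensemble.

    ``pdc[d, f, t]`` with direction axis d = 0 for channel0 -> channel1
    (NC driving HIPP when channel order is (NC, HIPP)) and d = 1 for the
    reverse; NaN where the window was invalid or factorization failed.
    """

    pdc: np.ndarray  # (2, n_freqs, n_times)
    freqs_hz: np.ndarray
    times_s: np.ndarray
    window_len_s: float
    step_s: float
    n_invalid: int = 0


def csd_from_tfr_window(coeffs: np.ndarray, sel: np.ndarray) -> np.ndarray:
    """Trial- and time-averaged cross-spectral matrices from wavelet
    coefficients.

    ``coeffs``: complex (n_trials, n_ch, n_freqs, n_times); ``sel``:
    boolean over the time axis.  Returns (n_freqs, n_ch, n_ch).
    """
    w = coeffs[:, :, :, sel]  # trials x ch x freq x t_in_window
    return np.einsum("aift,ajft->fij", w, np.conj(w)) / (
        w.shape[0] * max(w.shape[3], 1))


def pdc(tfr: TFRStack, band_pad_hz: float = 0.0,
        window_len_s: float = 0.512, step_s: float = 0.020,
        t_range_s: tuple[float, float] = (-1.0, 1.0),
        tol: float = 1e-9, max_iter: int = 200) -> PDCResult:
    """Sliding-window non-parametric PDC on a two-channel TFR stack.

    For each 512 ms window (stepped by 20 ms over ``t_range_s``), the
    trial-averaged wavelet cross-spectral matrix over the window is
    factorized (Wilson) and the PDC of Ā = H⁻¹ extracted; the two
    off-diagonal terms are returned per direction.  The CSD grid is the
    wavelet frequency grid extended down to 0 Hz by nearest-value padding,
    treated as the full band of an equivalent low-rate process.
    """
    if tfr.coeffs.shape[1] != 2:
        raise ValueError("PDC requires exactly two channels")
    n_trials = tfr.coeffs.shape[0]
    if n_trials < 30:
        logger.warning("PDC on only %d trials; estimates may be unstable",
                       n_trials)
    freqs = tfr.freq_axis_hz
    step_f = freqs[1] - freqs[0]
    n_pad = int(round(freqs[0] / step_f))  # bins to extend down to 0 Hz
    full_freqs = np.concatenate([np.arange(n_pad) * step_f, freqs])

    centers = np.arange(t_range_s[0], t_range_s[1] + 1e-9, step_s)
    out = np.full((2, len(freqs), len(centers)), np.nan)
    n_invalid = 0
    half = window_len_s / 2
    coeffs = tfr.coeffs
    for ti, c in enumerate(centers):
        sel = (tfr.time_axis_s >= c - half) & (tfr.time_axis_s <= c + half)
        if not sel.any():
            n_invalid += 1
            continue
        w = coeffs[:, :, :, sel]
        if np.isnan(w).any():
            n_invalid += 1
            continue
        # S[f] = mean over trials and window time of the channel outer
        # product of the wavelet coefficients
        S = csd_from_tfr_window(coeffs, sel)
        S_ext = np.concatenate(
            [np.repeat(S[:1], n_pad, axis=0), S], axis=0)
        pi, converged = pdc_from_csd(S_ext, tol=tol, max_iter=max_iter)
        if not converged:
            n_invalid += 1
            logger.info("Wilson factorization did not converge in window "
                        "%.3f s", c)
            continue
        pi = pi[n_pad:]
        out[0, :, ti] = pi[:, 1, 0]  # ch0 -> ch1
        out[1, :, ti] = pi[:, 0, 1]  # ch1 -> ch0
    return PDCResult(pdc=out, freqs_hz=freqs.copy(), times_s=centers,
                     window_len_s=window_len_s, step_s=step_s,
                     n_invalid=n_invalid)


def pdc_direction_timecourse(
    pdc_ripple: PDCResult,
    pdc_controls: list[PDCResult],
    band: tuple[float, float] = (12.0, 16.0),
    coherence_mask: np.ndarray | None = None,
) -> dict:
    """z-scored direction contrast: z(NC→HIPP) − z(HIPP→NC) over time.

    Each direction's band-mean PDC time course is z-scored against the
    distribution of the same quantity over the control sets, per time
    point; the difference is positive when the first channel drives the
    second.  Time points where the control SD vanishes are NaN; an optional
    boolean mask (e.g. where band coherence is significantly positive)
    restricts the reported values.
    """
    def _band_tc(res: PDCResult) -> np.ndarray:
        return np.stack([band_mean(res.pdc[d], res.freqs_hz, band)
                         for d in (0, 1)])

    emp = _band_tc(pdc_ripple)  # (2, n_times)
    ctl = np.stack([_band_tc(r) for r in pdc_controls])  # (n_sets, 2, T)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(ctl, axis=0)
    sd = np.nanstd(ctl, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (emp - mean) / sd
    z[:, np.nan_to_num(sd, nan=0.0).min(axis=0) <= 0] = np.nan
    z_diff = z[0] - z[1]
    if coherence_mask is not None:
        z_diff = np.where(coherence_mask, z_diff, np.nan)
    return dict(z_nc_to_hipp=z[0], z_hipp_to_nc=z[1], z_diff=z_diff,
                times_s=pdc_ripple.times_s)
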