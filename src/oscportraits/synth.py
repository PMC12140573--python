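"""Synthetic trial tables and raw signals with known ground truth.

The generator emulates the statistical structure of the single-trial
portrait data: 24 subjects performing ~100-800 trials spread over six trial
categories, with 48 oscillatory elements per trial that (i) covary on a
low-dimensional latent manifold whose orientation is category-specific,
(ii) carry a per-subject random intercept, (iii) receive an exogenous drive
from the trial's movement error, and (iv) are read out into movement
duration.  Per trial i of category c and subject s:

    x_i = mu_c + u_s + A_c z_i + gamma_c err_i + eta_i,
    A_c = B + delta R_c,           z_i ~ N(0, I_k)
    u_s ~ N(0, tau^2 I),           eta_i ~ N(0, sigma^2 I)
    duration_i = d0 + c (v . x_i + N(0, duration_noise_sd^2))

R_c is a seeded orthonormal 48 x k perturbation fixed per category, so the
category manifolds differ by rotation rather than scale.  Category mean
offsets are tied to the same perturbation scale, mu_c = delta * m_c with
m_c a seeded unit direction: per-element marginals then stay heavily
overlapping while the 48-dimensional portraits separate, the regime the
downstream analyses are designed to expose.  Hit/Miss labels are coupled to
|err| vs. ``hit_threshold`` by default (success means a small direction
error); the error distribution is then truncated-normal and the closed-form
covariance used by :func:`ground_truth_ec` accounts for it.

Because the model is jointly Gaussian (given category), the population
regression coefficients of each element on the other 47 are available in
closed form from the precision matrix, giving an exact oracle for the
effective-connectivity stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ec import ECMatrix
from .elements import (
    BANDS,
    CATEGORIES,
    EPOCHS,
    HIT_CATEGORIES,
    N_ELEMENTS,
    REGIONS,
    BandEpochSpec,
    ElementIndex,
    element_columns,
    element_labels,
)
from .io import META_COLUMNS, SignalSet, TrialSignals

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_portraits",
    "ground_truth_ec",
    "model_covariance",
    "generate_signals",
    "default_backbone",
    "default_error_loadings",
    "default_duration_readout",
]

#: Default per-subject trial counts; the per-category imbalance mirrors a
#: session dominated by unrotated and strategy trials, with rarer catch
#: (Ct) and after-rotation (AR) trials.
DEFAULT_TRIALS = {
    "NR-Hit": 120,
    "NR-Miss": 60,
    "RS-Hit": 100,
    "RS-Miss": 80,
    "Ct-Miss": 40,
    "AR-Miss": 40,
}

# fixed sub-stream ids so structural draws never depend on trial counts
_STREAM_STRUCTURE = 0
_STREAM_CATEGORY = 1
_STREAM_TRIALS = 2
_STREAM_SIGNALS = 3


def _beta_erd_factor(loading: float = 0.9) -> np.ndarray:
    """Deterministic sensorimotor beta desynchronization/rebound factor.

    Beta power over the sensorimotor regions (IC3/IC4) is suppressed
    during movement and rebounds afterwards; this factor loads the six
    sensorimotor beta elements with the classic Pre +, During -, Post +
    signature and anchors the covariance of the elements that the
    duration readout taps.
    """
    col = np.zeros(N_ELEMENTS)
    sign = {"Pre": 1.0, "During": -1.0, "Post": 1.0}
    for r in ("IC3", "IC4"):
        for e, s in sign.items():
            col[ElementIndex(r, e, "beta").column] = loading * s
    return col


def default_backbone(
    k: int = 5, block_loading: float = 0.6, seed: int = 0, scale: float = 0.8
) -> np.ndarray:
    """Structured 48 x k latent loading matrix.

    The last factor is the deterministic sensorimotor beta ERD/ERS
    pattern; each remaining factor mixes a label-structured pattern
    (elements sharing a region, band or epoch load identically; factors
    cycle through the three axes) with unstructured noise, with
    ``block_loading`` in [0, 1] setting the mix.  Larger values produce
    more homophilic connectivity.
    """
    rng = np.random.default_rng([seed, _STREAM_STRUCTURE])
    axes = ["spatial", "spectral", "temporal"]
    B = np.zeros((N_ELEMENTS, k))
    n_random = k - 1 if k >= 2 else k
    for f in range(n_random):
        labels = element_labels(axes[f % 3])
        levels = sorted(set(labels))
        per_level = {lv: rng.normal() for lv in levels}
        structured = np.array([per_level[l] for l in labels])
        structured /= max(np.abs(structured).max(), 1e-12)
        noise = rng.normal(size=N_ELEMENTS)
        noise /= max(np.abs(noise).max(), 1e-12)
        col = block_loading * structured + (1.0 - block_loading) * noise
        B[:, f] = scale * col
    if k >= 2:
        B[:, k - 1] = _beta_erd_factor()
    if np.linalg.matrix_rank(B) < k:
        raise ValueError("default backbone construction produced rank-deficient B")
    return B


def default_error_loadings(coupling: float = 3.0) -> dict[str, np.ndarray]:
    """Error drive concentrated on medial-frontal (IC1) During/Post elements.

    The same pattern is used for all six categories; the overall coupling
    can be scaled per call.  Concentrating the drive on a few elements
    makes the error node a genuine *driver*: many strong outgoing links,
    diffuse weak incoming ones.
    """
    gamma = np.zeros(N_ELEMENTS)
    for epoch in ("During", "Post"):
        for band in BANDS:
            gamma[ElementIndex("IC1", epoch, band).column] = coupling / np.sqrt(8)
    return {c: gamma.copy() for c in CATEGORIES}


def default_duration_readout(coupling: float = 0.9) -> np.ndarray:
    """Duration readout from sensorimotor (IC3/IC4) beta elements."""
    v = np.zeros(N_ELEMENTS)
    cols = [
        ElementIndex(r, e, "beta").column for r in ("IC3", "IC4") for e in EPOCHS
    ]
    for c in cols:
        v[c] = coupling / np.sqrt(len(cols))
    return v


@dataclass
class SynthConfig:
    """Parameters of the synthetic portrait generator.

    ``trials_per_category`` counts trials *per subject*.  All standard
    deviations are on the element (log-power) scale, whose residual SD is
    ``residual_sd`` (default 1), so every other scale reads as a fraction
    of single-element noise.
    """

    n_subjects: int = 24
    trials_per_category: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TRIALS)
    )
    n_latent: int = 5
    backbone: np.ndarray | None = None
    block_loading: float = 0.6
    category_perturbation: float = 0.6
    subject_intercept_sd: float = 0.5
    residual_sd: float = 1.0
    error_sd: float = 1.0
    error_loadings: dict[str, np.ndarray] | None = None
    category_means: dict[str, np.ndarray] | None = None
    duration_readout: np.ndarray | None = None
    duration_base: float = 1.2
    duration_scale: float = 0.1
    duration_noise_sd: float = 2.5
    hit_threshold: float = 1.0
    couple_labels: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.trials_per_category) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown category labels {sorted(bad)}")
        if self.category_perturbation < 0:
            raise ValueError("category_perturbation must be >= 0")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        for name in ("subject_intercept_sd", "error_sd", "duration_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.hit_threshold <= 0:
            raise ValueError("hit_threshold must be positive")
        if self.backbone is not None:
            B = np.asarray(self.backbone, dtype=float)
            if B.shape != (N_ELEMENTS, self.n_latent):
                raise ValueError(
                    f"backbone must be {N_ELEMENTS} x {self.n_latent}, got {B.shape}"
                )
            # all-zero backbone is allowed as the independent-elements
            # degenerate case; otherwise columns must be independent
            if B.any() and np.linalg.matrix_rank(B) < self.n_latent:
                raise ValueError("backbone must have full column rank")
            self.backbone = B
        if self.error_loadings is not None:
            for c, g in self.error_loadings.items():
                g = np.asarray(g, dtype=float)
                if g.shape != (N_ELEMENTS,):
                    raise ValueError(f"error_loadings[{c!r}] must have length {N_ELEMENTS}")
                self.error_loadings[c] = g
        if self.duration_readout is not None:
            v = np.asarray(self.duration_readout, dtype=float)
            if v.shape != (N_ELEMENTS,):
                raise ValueError(f"duration_readout must have length {N_ELEMENTS}")
            self.duration_readout = v

    # -- resolved (seed-dependent) structural parameters ------------------
    def resolve_backbone(self) -> np.ndarray:
        if self.backbone is not None:
            return self.backbone
        return default_backbone(self.n_latent, self.block_loading, self.seed)

    def resolve_error_loadings(self) -> dict[str, np.ndarray]:
        if self.error_loadings is not None:
            out = {c: np.zeros(N_ELEMENTS) for c in CATEGORIES}
            out.update(self.error_loadings)
            return out
        return default_error_loadings()

    def resolve_duration_readout(self) -> np.ndarray:
        if self.duration_readout is not None:
            return self.duration_readout
        return default_duration_readout()

    def category_rotation(self, category: str) -> np.ndarray:
        """Seeded orthonormal 48 x k perturbation R_c, fixed per category."""
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        idx = CATEGORIES.index(category)
        rng = np.random.default_rng([self.seed, _STREAM_CATEGORY, idx])
        R, _ = np.linalg.qr(rng.normal(size=(N_ELEMENTS, self.n_latent)))
        return R

    def category_loading(self, category: str) -> np.ndarray:
        """A_c = B + delta * R_c."""
        return self.resolve_backbone() + self.category_perturbation * self.category_rotation(category)

    def category_mean(self, category: str) -> np.ndarray:
        """mu_c = delta * m_c with m_c a seeded unit direction (or override)."""
        if self.category_means is not None and category in self.category_means:
            mu = np.asarray(self.category_means[category], dtype=float)
            if mu.shape != (N_ELEMENTS,):
                raise ValueError(f"category_means[{category!r}] must have length {N_ELEMENTS}")
            return mu
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        idx = CATEGORIES.index(category)
        rng = np.random.default_rng([self.seed, _STREAM_CATEGORY, idx, 1])
        m = rng.normal(size=N_ELEMENTS)
        m /= np.linalg.norm(m)
        return self.category_perturbation * m

    def error_variance(self, category: str) -> float:
        """Variance of the movement error actually generated for a category.

        With Hit/Miss label coupling the error is truncated normal
        (|err| < threshold for Hits, |err| >= threshold for Misses), which
        shrinks or inflates its variance relative to ``error_sd**2``.
        """
        if not self.couple_labels or self.error_sd == 0:
            return self.error_sd**2
        a = self.hit_threshold / self.error_sd
        if category in HIT_CATEGORIES:
            return self.error_sd**2 * stats.truncnorm.var(-a, a)
        tail = stats.truncnorm(a, np.inf)
        return self.error_sd**2 * (tail.var() + tail.mean() ** 2)


@dataclass
class GroundTruth:
    """Latent quantities behind a generated trial table (row-aligned)."""

    z: np.ndarray  # trials x k latent coordinates
    err: np.ndarray  # trials; the exogenous error drive
    subject_intercepts: dict[str, np.ndarray]  # subject -> 48-vector u_s
    loadings: dict[str, np.ndarray]  # category -> A_c
    means: dict[str, np.ndarray]  # category -> mu_c
    error_loadings: dict[str, np.ndarray]  # category -> gamma_c
    duration_readout: np.ndarray


def _draw_errors(
    config: SynthConfig, category: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    if config.error_sd == 0:
        return np.zeros(n)
    if not config.couple_labels:
        return rng.normal(0.0, config.error_sd, n)
    a = config.hit_threshold / config.error_sd
    if category in HIT_CATEGORIES:
        u = rng.random(n)
        # inverse-CDF sampling of the central truncation
        lo, hi = stats.norm.cdf(-a), stats.norm.cdf(a)
        return config.error_sd * stats.norm.ppf(lo + u * (hi - lo))
    # two-sided tail: random sign, magnitude from the upper tail
    u = rng.random(n)
    hi = stats.norm.sf(a)
    mag = config.error_sd * stats.norm.isf(u * hi)
    sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
    return sign * mag


def generate_portraits(config: SynthConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a trial table plus the ground truth that produced it.

    Identical configs (same seed) produce bit-identical tables.
    """
    rng = np.random.default_rng([config.seed, _STREAM_TRIALS])
    cats = [c for c in CATEGORIES if config.trials_per_category.get(c, 0) > 0]
    if not cats:
        raise ValueError("no categories with a positive trial count")
    A = {c: config.category_loading(c) for c in cats}
    mu = {c: config.category_mean(c) for c in cats}
    gamma = config.resolve_error_loadings()
    v = config.resolve_duration_readout()
    subjects = [f"S{j + 1:02d}" for j in range(config.n_subjects)]
    u_s = {
        s: rng.normal(0.0, config.subject_intercept_sd, N_ELEMENTS) for s in subjects
    }

    rows_meta, rows_x, rows_z, rows_err = [], [], [], []
    for s in subjects:
        for c in cats:
            n = config.trials_per_category[c]
            z = rng.normal(size=(n, config.n_latent))
            err = _draw_errors(config, c, n, rng)
            eta = rng.normal(0.0, config.residual_sd, (n, N_ELEMENTS))
            x = mu[c] + u_s[s] + z @ A[c].T + err[:, None] * gamma[c] + eta
            dur = config.duration_base + config.duration_scale * (
                x @ v + rng.normal(0.0, config.duration_noise_sd, n)
            )
            dur = np.maximum(dur, 0.45)
            for i in range(n):
                rows_meta.append((s, c, err[i], dur[i]))
            rows_x.append(x)
            rows_z.append(z)
            rows_err.append(err)

    X = np.vstack(rows_x)
    table = pd.DataFrame(rows_meta, columns=list(META_COLUMNS))
    table = pd.concat(
        [table, pd.DataFrame(X, columns=element_columns())], axis=1
    )
    truth = GroundTruth(
        z=np.vstack(rows_z),
        err=np.concatenate(rows_err),
        subject_intercepts=u_s,
        loadings=A,
        means=mu,
        error_loadings={c: gamma[c] for c in cats},
        duration_readout=v,
    )
    return table, truth


def model_covariance(config: SynthConfig, category: str) -> np.ndarray:
    """Closed-form within-subject covariance of the 48 elements.

    Sigma_c = A_c A_c' + var(err_c) gamma_c gamma_c' + sigma^2 I.  The
    subject intercept variance tau^2 is excluded: it is absorbed by the
    random intercepts downstream and does not enter the within-subject
    regression structure.
    """
    A = config.category_loading(category)
    gamma = config.resolve_error_loadings()[category]
    ve = config.error_variance(category)
    return (
        A @ A.T
        + ve * np.outer(gamma, gamma)
        + config.residual_sd**2 * np.eye(N_ELEMENTS)
    )


def ground_truth_ec(
    config: SynthConfig, category: str, standardized: bool = False
) -> ECMatrix:
    """Population regression coefficients of each element on the other 47.

    Row t, column s equals -Omega_ts / Omega_tt with Omega the precision
    matrix of the within-subject covariance; the diagonal is zero.  With
    ``standardized=True`` the covariance is first converted to a
    correlation matrix, matching the z-scored coefficients stored by
    :func:`oscportraits.ec.fit_ec`.
    """
    sigma = model_covariance(config, category)
    if standardized:
        d = np.sqrt(np.diag(sigma))
        sigma = sigma / np.outer(d, d)
    try:
        omega = np.linalg.inv(sigma)
    except np.linalg.LinAlgError:
        raise ValueError(
            f"model covariance for category {category!r} is singular"
        ) from None
    if not np.isfinite(omega).all() or np.linalg.cond(sigma) > 1e12:
        raise ValueError(f"model covariance for category {category!r} is singular")
    W = -omega / np.diag(omega)[:, None]
    np.fill_diagonal(W, 0.0)
    return ECMatrix(
        nodes=element_columns(),
        weights=W,
        n_bootstrap=0,
        provenance=f"ground-truth:{category}",
    )


# ---------------------------------------------------------------------------
# raw signal synthesis
# ---------------------------------------------------------------------------


def _band_noise(n: int, fs: float, lo: float, hi: float, rng) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [lo, hi] Hz."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (f >= lo) & (f <= hi)
    if not mask.any():
        raise ValueError(f"band [{lo}, {hi}] Hz is empty at n={n}, fs={fs}")
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(n: int, fs: float, rng) -> np.ndarray:
    """Unit-variance 1/f broadband noise."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(f)
    shaping[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * shaping, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _epoch_envelope(times, onset, offset, a_pre, a_dur, a_post, ramp=0.05):
    """Piecewise amplitude with raised-cosine crossfades at the boundaries."""

    def step(t, t0):
        s = np.clip((t - (t0 - ramp / 2)) / ramp, 0.0, 1.0)
        return 0.5 * (1.0 - np.cos(np.pi * s))

    t = np.asarray(times, dtype=float)
    return a_pre + (a_dur - a_pre) * step(t, onset) + (a_post - a_dur) * step(t, offset)


def generate_signals(
    config: SynthConfig,
    fs: float = 256.0,
    spec: BandEpochSpec | None = None,
    broadband: float = 0.25,
    amp_scale: float = 1.0,
    ramp: float = 0.05,
) -> SignalSet:
    """Synthesize per-trial, per-region time courses realizing the portraits.

    Each region's signal is a sum over the four bands of band-limited
    Gaussian noise whose epoch-wise amplitude is exp(element / 2) (elements
    are log-power), with 50-ms cosine ramps at movement onset/offset, plus
    1/f broadband noise at level ``broadband``.  The generating portrait
    table is attached so extraction can be validated against it.
    """
    if spec is None:
        spec = BandEpochSpec()
    top = max(hi for _, hi in spec.bands.values())
    if fs <= 2 * top:
        raise ValueError(f"fs={fs} must exceed twice the top band edge {top} Hz")
    table, _ = generate_portraits(config)
    rng = np.random.default_rng([config.seed, _STREAM_SIGNALS])
    cols = element_columns()
    out = SignalSet(trials=[], fs=fs, table=table)
    for i, row in table.iterrows():
        dur = float(row["duration"])
        if dur <= 0:
            raise ValueError(f"trial {i} has non-positive duration {dur}")
        n = int(round((dur + spec.pre_margin + spec.post_margin) * fs)) + 1
        times = -spec.pre_margin + np.arange(n) / fs
        data = np.zeros((len(REGIONS), n))
        for ri, region in enumerate(REGIONS):
            sig = broadband * _pink_noise(n, fs, rng) if broadband > 0 else np.zeros(n)
            for band, (lo, hi) in spec.bands.items():
                amps = [
                    amp_scale * np.exp(row[f"{region}_{e}_{band}"] / 2.0)
                    for e in EPOCHS
                ]
                env = _epoch_envelope(times, 0.0, dur, *amps, ramp=ramp)
                sig = sig + env * _band_noise(n, fs, lo, hi, rng)
            data[ri] = sig
        out.trials.append(
            TrialSignals(
                trial_id=int(i),
                subject=str(row["subject"]),
                category=str(row["category"]),
                onset=0.0,
                offset=dur,
                fs=fs,
                times=times,
                data=data,
                error=float(row["error"]),
                duration=dur,
            )
        )
    return out
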