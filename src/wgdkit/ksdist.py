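"""Ks-distribution modeling and molecular-clock conversion.

A Ks distribution built from filtered homolog pairs is modeled as a mixture
of Gaussian components fitted by EM; each component mean is a candidate
whole-genome-duplication (or speciation) peak.  Peaks are converted to
divergence times with a strict molecular clock, T = Ks / (2µ), using the
monocot synonymous substitution rate µ = 6.5e-9 substitutions/site/year by
default, and reported as a (min, mode, max) window of mode ± one component
standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.mixture import GaussianMixture

KS_MIN = 0.01
KS_MAX = 3.0


def filter_ks(ks_values, ks_min: float = KS_MIN, ks_max: float = KS_MAX):
    """Keep Ks values in [ks_min, ks_max); drop NaN/saturated (None) entries.

    Values below ks_min are near-identical copies (allelic noise or very
    recent duplicates); values at or above ks_max are saturated.  The filter
    is idempotent.
    """
    out = []
    for v in ks_values:
        if v is None:
            continue
        v = float(v)
        if np.isnan(v):
            continue
        if ks_min <= v < ks_max:
            out.append(v)
    return np.asarray(out, dtype=float)


@dataclass
class MixtureComponent:
    weight: float
    mean: float
    stdev: float


@dataclass
class MixtureFit:
    """Fitted Gaussian mixture over a Ks distribution.

    Components are sorted by mean.  ``bootstrap_mean_sd`` holds, per
    component, the standard deviation of the component mean across bootstrap
    refits (resampling the Ks vector with replacement, k held fixed).
    """

    components: list[MixtureComponent]
    log_likelihood: float
    converged: bool
    k: int
    bic: dict[int, float] = field(default_factory=dict)
    bootstrap_mean_sd: list[float] = field(default_factory=list)

    @property
    def means(self) -> list[float]:
        return [c.mean for c in self.components]

    @property
    def weights(self) -> list[float]:
        return [c.weight for c in self.components]


def fit_mixture(
    ks_values,
    k_range=(1, 2, 3, 4, 5),
    convergence_tol: float = 0.001,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> MixtureFit:
    """Fit a Gaussian mixture to Ks values by EM, choosing k by BIC.

    EM iterates until the log-likelihood change drops below
    ``convergence_tol`` (default 0.001); the number of components is chosen
    by BIC over ``k_range``; parameter uncertainty comes from refitting
    ``n_bootstrap`` resamples (with replacement) at the selected k.
    Deterministic under a fixed seed.  Requires >= 50 values.
    """
    values = np.asarray(list(ks_values), dtype=float).reshape(-1, 1)
    if values.shape[0] < 50:
        raise ValueError(
            f"need >= 50 Ks values to fit a mixture, got {values.shape[0]}"
        )
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range or k_range[0] < 1 or k_range[-1] > 5:
        raise ValueError("k_range must be within [1, 5]")
    rng = np.random.default_rng(seed)
    # the convergence criterion applies to the change in *total* log
    # likelihood between EM iterations; sklearn's tol is per-sample
    sk_tol = convergence_tol / values.shape[0]
    bics: dict[int, float] = {}
    fits: dict[int, GaussianMixture] = {}
    for k in k_range:
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            tol=sk_tol,
            n_init=5,
            max_iter=2000,
            random_state=int(rng.integers(2**31 - 1)),
        )
        gm.fit(values)
        fits[k] = gm
        bics[k] = float(gm.bic(values))
    best_k = min(bics, key=bics.get)
    best = fits[best_k]

    order = np.argsort(best.means_.ravel())
    components = [
        MixtureComponent(
            weight=float(best.weights_[i]),
            mean=float(best.means_[i, 0]),
            stdev=float(np.sqrt(best.covariances_[i, 0, 0])),
        )
        for i in order
    ]

    boot_means = []
    n = values.shape[0]
    for _ in range(int(n_bootstrap)):
        sample = values[rng.integers(0, n, size=n)]
        gm = GaussianMixture(
            n_components=best_k,
            covariance_type="full",
            tol=sk_tol,
            n_init=1,
            max_iter=2000,
            means_init=best.means_,
            weights_init=best.weights_,
            precisions_init=best.precisions_,
            random_state=int(rng.integers(2**31 - 1)),
        )
        try:
            gm.fit(sample)
        except ValueError:
            continue
        boot_means.append(np.sort(gm.means_.ravel()))
    boot_sd = (
        list(np.std(np.array(boot_means), axis=0, ddof=1))
        if len(boot_means) > 1
        else [float("nan")] * best_k
    )

    return MixtureFit(
        components=components,
        log_likelihood=float(best.score(values) * n),
        converged=bool(best.converged_),
        k=best_k,
        bic=bics,
        bootstrap_mean_sd=[float(s) for s in boot_sd],
    )


@dataclass(frozen=True)
class ClockModel:
    """Strict molecular clock: mu substitutions per synonymous site per year."""

    mu: float = 6.5e-9

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("substitution rate mu must be positive")


DEFAULT_CLOCK = ClockModel()


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), ROUND_HALF_UP))


def ks_to_mya(ks: float, clock: ClockModel = DEFAULT_CLOCK) -> float:
    """Convert a Ks value to million years: T = Ks / (2µ), half-up to 0.1."""
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    return _round1(ks / (2.0 * clock.mu) / 1e6)


@dataclass
class DivergenceEstimate:
    """Divergence-time window (Mya, one decimal) for one Ks peak."""

    min_mya: float
    mode_mya: float
    max_mya: float
    floored: bool = False

    def __post_init__(self):
        if not (self.min_mya <= self.mode_mya <= self.max_mya):
            raise ValueError("divergence window must satisfy min <= mode <= max")


def peak_interval(
    component, clock: ClockModel = DEFAULT_CLOCK
) -> DivergenceEstimate:
    """Clock-convert a (mean, stdev) Ks peak into a (min, mode, max) window.

    ``component`` is anything with ``mean``/``stdev`` attributes or a
    (mean, stdev) tuple.  A lower bound below Ks = 0 is floored at zero and
    flagged.
    """
    if hasattr(component, "mean"):
        mean, stdev = float(component.mean), float(component.stdev)
    else:
        mean, stdev = float(component[0]), float(component[1])
    if stdev < 0:
        raise ValueError("stdev must be >= 0")
    lo = mean - stdev
    floored = lo < 0
    return DivergenceEstimate(
        min_mya=ks_to_mya(max(lo, 0.0), clock),
        mode_mya=ks_to_mya(mean, clock),
        max_mya=ks_to_mya(mean + stdev, clock),
        floored=floored,
    )
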