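"""Circular statistics for stroke-phase samples.

Phase samples (degrees of a stroke cycle) are classified by a fixed decision
procedure:

1. **Hermans-Rasson (HR) test** for any departure from circular uniformity —
   sensitive to non-axial, bimodal alternatives that Rayleigh's test misses.
   The statistic is the corrected pairwise form

       T = (1/n) * sum_ij [ |pi - ||th_i - th_j|| | - pi/2
                            - 2.895 * (|sin(th_i - th_j)| - 2/pi) ],

   with p-values from seeded Monte-Carlo simulation of uniform samples.
2. If non-uniform (HR p < alpha), a **von Mises goodness-of-fit check**
   (Watson U^2 against the ML-fitted von Mises, parametric bootstrap), since a
   von Mises distribution is the premise of Rayleigh's test.
3. If the fit holds, **Rayleigh's test** for unimodality.  HR-significant but
   Rayleigh-non-significant samples are classified non-uniform *multimodal*
   (e.g. a mixture of in-phase and out-of-phase strokes) and no mean is
   reported; HR- and Rayleigh-significant samples are non-uniform *unimodal*
   and get a circular mean and angular variance (1 - mean resultant length).

Group comparisons follow the same conventions: Watson-Williams F tests for
differences in angular mean, Kruskal-Wallis on per-observation angular
dispersion (absolute circular distance to the own-group mean) for differences
in variability, and Bonferroni correction for pairwise follow-ups.

Degrees are the user-facing unit throughout; radians are internal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "CircSample",
    "CircTestResult",
    "hermans_rasson_statistic",
    "hermans_rasson_test",
    "rayleigh_test",
    "vonmises_check",
    "classify_distribution",
    "circular_mean_variance",
    "circular_dispersion",
    "watson_williams",
    "dispersion_compare",
    "bonferroni",
]

logger = logging.getLogger(__name__)

UNIFORM = "uniform"
MULTIMODAL = "nonuniform_multimodal"
UNIMODAL = "nonuniform_unimodal"


@dataclass
class CircSample:
    """Phase angles in degrees with their grouping keys."""

    angles_deg: np.ndarray
    keys: dict = field(default_factory=dict)

    def __post_init__(self):
        a = np.asarray(self.angles_deg, float)
        if not np.all(np.isfinite(a)):
            raise ValueError("angles must be finite")
        self.angles_deg = np.mod(a, 360.0)

    def __len__(self):
        return len(self.angles_deg)


@dataclass
class CircTestResult:
    """Outcome of the uniform / multimodal / unimodal decision procedure."""

    n: int
    classification: str
    hr_stat: float | None = None
    hr_p: float | None = None
    vonmises_ok: bool | None = None
    vonmises_p: float | None = None
    rayleigh_R: float | None = None
    rayleigh_p: float | None = None
    circular_mean_deg: float | None = None
    angular_variance: float | None = None

    def __post_init__(self):
        has_mean = self.circular_mean_deg is not None
        if has_mean != (self.classification == UNIMODAL):
            raise ValueError(
                "circular mean is reported iff the sample is unimodal")


def _rad(angles_deg) -> np.ndarray:
    return np.radians(np.asarray(angles_deg, float))


def _resultant(rad: np.ndarray) -> tuple[float, float]:
    """(mean resultant length R_bar, mean direction in radians)."""
    z = np.exp(1j * rad).mean()
    return float(np.abs(z)), float(np.angle(z))


# ---------------------------------------------------------------------------
# Hermans-Rasson
# ---------------------------------------------------------------------------

def hermans_rasson_statistic(angles_deg: np.ndarray) -> float:
    """Corrected pairwise HR statistic (larger = less uniform)."""
    rad = _rad(angles_deg)
    return float(_hr_batch(rad[None, :])[0])


def _hr_batch(rad: np.ndarray) -> np.ndarray:
    """HR statistics for a batch of samples shaped (B, n)."""
    d = rad[:, :, None] - rad[:, None, :]
    t = np.abs(np.abs(d) - np.pi) - np.pi / 2
    t -= 2.895 * (np.abs(np.sin(d)) - 2.0 / np.pi)
    return t.sum(axis=(1, 2)) / rad.shape[1]


def hermans_rasson_test(angles_deg: np.ndarray, n_mc: int = 9999,
                        seed: int | np.random.Generator = 0
                        ) -> tuple[float, float]:
    """HR non-uniformity test with a Monte-Carlo p-value.

    p = (1 + #{uniform-sample statistics >= observed}) / (n_mc + 1);
    deterministic for a fixed seed.
    """
    angles = np.asarray(angles_deg, float)
    n = len(angles)
    if n < 4:
        raise ValueError("Hermans-Rasson test needs n >= 4")
    if n_mc < 999:
        raise ValueError("n_mc must be >= 999")
    obs = hermans_rasson_statistic(angles)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    count = 0
    chunk = max(1, int(2_000_000 / (n * n)))
    done = 0
    while done < n_mc:
        b = min(chunk, n_mc - done)
        sims = rng.uniform(0.0, 2 * np.pi, size=(b, n))
        count += int(np.sum(_hr_batch(sims) >= obs))
        done += b
    p = (1.0 + count) / (n_mc + 1.0)
    return obs, p


# ---------------------------------------------------------------------------
# Rayleigh
# ---------------------------------------------------------------------------

def rayleigh_test(angles_deg: np.ndarray) -> tuple[float, float]:
    """Rayleigh unimodality test: (mean resultant length R_bar, p).

    p uses the standard large-sample approximation with the small-sample
    correction terms.
    """
    rad = _rad(angles_deg)
    n = len(rad)
    if n < 3:
        raise ValueError("Rayleigh test needs n >= 3")
    rbar, _ = _resultant(rad)
    z = n * rbar ** 2
    p = np.exp(-z) * (1 + (2 * z - z ** 2) / (4 * n)
                      - (24 * z - 132 * z ** 2 + 76 * z ** 3 - 9 * z ** 4)
                      / (288 * n ** 2))
    return rbar, float(np.clip(p, 0.0, 1.0))


# ---------------------------------------------------------------------------
# von Mises goodness of fit
# ---------------------------------------------------------------------------

def _a1inv(rbar: float) -> float:
    """Invert A(kappa) = I1(kappa)/I0(kappa) = rbar (ML kappa estimate)."""
    if rbar <= 0:
        return 0.0
    if rbar >= 0.999:       # asymptotic regime: A(kappa) ~ 1 - 1/(2*kappa)
        return float(min(0.5 / (1.0 - rbar), 1e8))
    # Fisher's piecewise starting value, refined by root finding
    if rbar < 0.53:
        k0 = 2 * rbar + rbar ** 3 + 5 * rbar ** 5 / 6
    elif rbar < 0.85:
        k0 = -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    else:
        k0 = 1.0 / (rbar ** 3 - 4 * rbar ** 2 + 3 * rbar)
    k0 = min(max(k0, 1e-6), 700.0)

    def f(k):
        return special.i1e(k) / special.i0e(k) - rbar

    lo, hi = k0 / 4, min(k0 * 4, 1e3)
    try:
        if f(lo) * f(hi) < 0:
            return float(optimize.brentq(f, lo, hi, xtol=1e-10))
    except ValueError:
        pass
    return float(k0)


def _fit_vonmises(rad: np.ndarray) -> tuple[float, float]:
    rbar, mu = _resultant(rad)
    return mu, _a1inv(rbar)


def _watson_u2(rad: np.ndarray, mu: float, kappa: float) -> float:
    n = len(rad)
    u = np.sort(stats.vonmises.cdf(np.mod(rad - mu + np.pi, 2 * np.pi) - np.pi,
                                   kappa))
    i = np.arange(1, n + 1)
    ubar = u.mean()
    return float(np.sum((u - (2 * i - 1) / (2 * n)) ** 2)
                 - n * (ubar - 0.5) ** 2 + 1.0 / (12 * n))


def vonmises_check(angles_deg: np.ndarray, alpha: float = 0.05,
                   n_boot: int = 200,
                   seed: int | np.random.Generator = 0
                   ) -> tuple[bool, float]:
    """Watson U^2 goodness of fit of the von Mises family.

    The null distribution of U^2 with estimated parameters is obtained by
    parametric bootstrap from the fitted von Mises.  Returns
    (fit_not_rejected_at_alpha, bootstrap_p).
    """
    rad = _rad(angles_deg)
    n = len(rad)
    if n < 5:
        raise ValueError("von Mises check needs n >= 5")
    mu, kappa = _fit_vonmises(rad)
    obs = _watson_u2(rad, mu, kappa)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    count = 0
    for _ in range(n_boot):
        sim = rng.vonmises(mu, kappa, size=n) if kappa > 0 else \
            rng.uniform(-np.pi, np.pi, size=n)
        mu_b, kap_b = _fit_vonmises(sim)
        if _watson_u2(sim, mu_b, kap_b) >= obs:
            count += 1
    p = (1.0 + count) / (n_boot + 1.0)
    return p >= alpha, p


# ---------------------------------------------------------------------------
# mean / variance / dispersion
# ---------------------------------------------------------------------------

def circular_mean_variance(angles_deg: np.ndarray) -> tuple[float, float]:
    """(circular mean in degrees [0, 360), angular variance 1 - R_bar)."""
    rad = _rad(angles_deg)
    if len(rad) < 1:
        raise ValueError("need at least one angle")
    rbar, mu = _resultant(rad)
    if rbar < 1e-12:
        raise ValueError("circular mean undefined: zero resultant length")
    mean = float(np.degrees(mu) % 360.0)
    if mean >= 360.0:  # guard the float wrap of tiny negative angles
        mean = 0.0
    return mean, float(1.0 - rbar)


def circular_dispersion(angles_deg: np.ndarray) -> np.ndarray:
    """Absolute circular distance (deg, <= 180) to the sample's own mean."""
    mean, _ = circular_mean_variance(angles_deg)
    d = np.abs(np.mod(np.asarray(angles_deg, float) - mean + 180.0, 360.0)
               - 180.0)
    return d


# ---------------------------------------------------------------------------
# classification procedure
# ---------------------------------------------------------------------------

def classify_distribution(angles_deg: np.ndarray, alpha: float = 0.05,
                          n_mc: int = 9999, n_boot: int = 200,
                          seed: int | np.random.Generator = 0,
                          skip_hr: bool = False) -> CircTestResult:
    """Uniform / non-uniform-multimodal / non-uniform-unimodal classification.

    HR test first (skippable via ``skip_hr`` for within-trial screening where
    only unimodal in- or out-of-phase behaviour is in question); if
    non-uniform, a von Mises check gates Rayleigh's test.  Mean and angular
    variance are reported only for unimodal samples.
    """
    angles = np.asarray(angles_deg, float)
    n = len(angles)
    if n < 5:
        raise ValueError("classification needs n >= 5")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    hr_stat = hr_p = None
    if not skip_hr:
        hr_stat, hr_p = hermans_rasson_test(angles, n_mc=n_mc, seed=rng)
        if hr_p >= alpha:
            return CircTestResult(n=n, classification=UNIFORM,
                                  hr_stat=hr_stat, hr_p=hr_p)

    vm_ok, vm_p = vonmises_check(angles, alpha=alpha, n_boot=n_boot, seed=rng)
    if not vm_ok:
        return CircTestResult(n=n, classification=MULTIMODAL,
                              hr_stat=hr_stat, hr_p=hr_p,
                              vonmises_ok=vm_ok, vonmises_p=vm_p)

    rbar, r_p = rayleigh_test(angles)
    if r_p < alpha:
        mean, var = circular_mean_variance(angles)
        return CircTestResult(n=n, classification=UNIMODAL,
                              hr_stat=hr_stat, hr_p=hr_p,
                              vonmises_ok=vm_ok, vonmises_p=vm_p,
                              rayleigh_R=rbar, rayleigh_p=r_p,
                              circular_mean_deg=mean, angular_variance=var)
    return CircTestResult(n=n, classification=MULTIMODAL,
                          hr_stat=hr_stat, hr_p=hr_p,
                          vonmises_ok=vm_ok, vonmises_p=vm_p,
                          rayleigh_R=rbar, rayleigh_p=r_p)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def watson_williams(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Watson-Williams F test for equality of angular means.

    Uses the standard correction factor 1 + 3/(8*kappa) with kappa estimated
    from the pooled within-group resultant.  The common-concentration
    assumption is logged when the pooled resultant is low.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rads = [_rad(g) for g in groups]
    ns = np.array([len(r) for r in rads])
    if np.any(ns < 5):
        raise ValueError("each group needs n >= 5")
    Rs = []
    for r in rads:
        rbar, _ = _resultant(r)
        if rbar < 1e-12:
            raise ValueError("a group has an undefined circular mean")
        Rs.append(rbar * len(r))
    Rs = np.array(Rs)
    N = int(ns.sum())
    pooled = np.concatenate(rads)
    R_all = _resultant(pooled)[0] * N
    k = len(groups)

    rw = float(Rs.sum() / N)
    if rw < 0.45:
        logger.warning(
            "Watson-Williams concentration assumption questionable "
            "(pooled resultant %.2f < 0.45)", rw)
    kappa = _a1inv(rw)
    corr = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    num = (Rs.sum() - R_all) / (k - 1)
    den = (N - Rs.sum()) / (N - k)
    if den <= 0:
        return float("inf"), 0.0
    F = float(corr * num / den)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, k - 1, N - k))
    return F, p


def dispersion_compare(groups: Sequence[np.ndarray]):
    """Kruskal-Wallis on angular dispersion, plus Bonferroni pairwise table.

    Dispersion is each observation's absolute circular distance to its own
    group's circular mean.  Returns (H, p, pairwise DataFrame).
    """
    import pandas as pd

    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    disps = [circular_dispersion(g) for g in groups]
    H, p = stats.kruskal(*disps)
    pairs = []
    m = len(groups) * (len(groups) - 1) // 2
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            U, praw = stats.mannwhitneyu(disps[i], disps[j],
                                         alternative="two-sided")
            pairs.append((i, j, float(U), float(praw),
                          bonferroni([praw], m)[0]))
    table = pd.DataFrame(pairs, columns=["group_i", "group_j", "U",
                                         "p_raw", "p_adj"])
    return float(H), float(p), table


def bonferroni(pvalues: Sequence[float], family_size: int) -> list[float]:
    """min(1, p * family_size) for each p."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    out = []
    for p in pvalues:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, float(p) * family_size))
    return out
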