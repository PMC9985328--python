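"""Closed-form selective-sweep model for haplotype blocks.

A block of |K| identical haplotypes at sample frequency y spanning genetic
length d cM is dated with a recombination clock: under a hard sweep with
additive selection s, the haplotype rose from initial frequency
y0 = 1/(2 Ne) along a logistic trajectory, taking

    t = (1/s) * ln( y (1 - y0) / (y0 (1 - y)) )   generations,

and the probability that one flanking interval of recombination fraction r
survives unbroken over the sweep is

    C(s, r, y) = e^{-r t} (1 - y0 (1 - e^{s t}))^{r/s},

which simplifies exactly to (y0/y)^{r/s}.  Treating the 2|K| block edges as
independent (a star genealogy) gives a composite likelihood whose log is

    ln L(s | r, y) = 2|K| ( (r/s) ln(y0/y) + ln(1 - (y0/y)^{dr/s}) ),

with dr the recombination fraction between contiguous SNPs; it is maximized
in closed form by

    s_hat = dr / ln(r / (dr + r)) * ln(y0 / y).

All likelihood math runs in log space; underflow yields -inf, never NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelConfig",
    "SelectionEstimate",
    "haldane",
    "inverse_haldane",
    "no_recomb_prob",
    "sweep_age",
    "log_composite_likelihood",
    "mcl_selection",
    "mcl_selection_arrays",
    "mean_delta_r",
]


def haldane(d_cm):
    """Haldane map function: cM distance -> recombination fraction in [0, 0.5)."""
    d = np.asarray(d_cm, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("negative map distance")
    r = -np.expm1(-2.0 * d / 100.0) / 2.0
    return float(r) if np.isscalar(d_cm) else r


def inverse_haldane(r):
    """Recombination fraction -> cM distance (inverse of :func:`haldane`)."""
    r = np.asarray(r, dtype=np.float64)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    return -50.0 * np.log1p(-2.0 * r)


@dataclass
class ModelConfig:
    """Model parameters shared across all blocks of one scan.

    ne is the effective population size in diploid individuals; the default
    10,000 is a deliberately conservative choice for humans — with
    uncertain demography, smaller ne yields lower estimates and stricter
    filters.  delta_r is the recombination fraction between contiguous
    SNPs, normally the Haldane transform of the mean inter-SNP map
    distance of the (MAF-filtered) input.  s_min is the smallest selection
    coefficient worth reporting and parametrizes the drift filter.
    """

    ne: float = 10_000.0
    delta_r: float = 1e-6
    s_min: float = 0.005

    def __post_init__(self) -> None:
        if self.ne < 2:
            raise ValueError("ne must be >= 2")
        if not 0 < self.delta_r < 0.5:
            raise ValueError("delta_r must lie in (0, 0.5)")
        if self.s_min <= 0:
            raise ValueError("s_min must be positive")

    @property
    def y0_single(self) -> float:
        """Initial frequency of a single haplotype, 1/(2 Ne)."""
        return 1.0 / (2.0 * self.ne)

    @property
    def y0_pair(self) -> float:
        """Initial frequency of two haplotype copies, 1/Ne."""
        return 1.0 / self.ne


@dataclass
class SelectionEstimate:
    """Maximum-composite-likelihood estimate for one block."""

    s_hat: float
    log_cl: float
    t_hat1: float  # sweep age with y0 = 1/(2 Ne), generations
    t_hat2: float  # sweep age with y0 = 1/Ne, generations
    estimable: bool = True

    @property
    def t_hat(self) -> float:
        return self.t_hat1


def mean_delta_r(positions_cm: np.ndarray) -> float:
    """Default delta_r: Haldane transform of the mean inter-SNP cM distance."""
    cm = np.asarray(positions_cm, dtype=np.float64)
    if len(cm) < 2:
        raise ValueError("need at least two sites to compute delta_r")
    mean_d = (cm[-1] - cm[0]) / (len(cm) - 1)
    if mean_d <= 0:
        raise ValueError("degenerate genetic map: zero total cM length")
    return float(haldane(mean_d))


def sweep_age(s, y, y0):
    """Time in generations for the logistic sweep to reach frequency y from y0."""
    s = np.asarray(s, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if np.any(s <= 0):
        raise ValueError("selection coefficient must be positive")
    if np.any(y <= y0):
        raise ValueError("sweep model undefined for y <= y0")
    if np.any(y >= 1):
        raise ValueError("y = 1 must be substituted by 1 - 1/(2k) before dating")
    t = (np.log(y) + np.log1p(-y0) - np.log(y0) - np.log1p(-y)) / s
    return float(t) if t.ndim == 0 else t


def no_recomb_prob(s, r, y, y0):
    """Probability that an interval of recombination fraction r survives the sweep.

    Evaluated in log space:
    ln C = -r t + (r/s) ln(1 - y0 (1 - e^{s t}))
         = (r/s) ln(y0 + (1 - y0) e^{-s t}),
    with t the sweep age.  Equals (y0/y)^{r/s} exactly.
    """
    s = np.asarray(s, dtype=np.float64)
    r = np.asarray(r, dtype=np.float64)
    if np.any(s <= 0):
        raise ValueError("selection coefficient must be positive")
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    t = sweep_age(s, y, y0)
    ln_c = (r / s) * np.log(y0 + (1.0 - y0) * np.exp(-s * t))
    out = np.exp(ln_c)
    return float(out) if out.ndim == 0 else out


def log_composite_likelihood(s, r, y, k_block, cfg: ModelConfig):
    """ln L(s | r, y) for a block of k_block haplotypes; -inf on underflow."""
    s = np.asarray(s, dtype=np.float64)
    if np.any(s <= 0):
        raise ValueError("selection coefficient must be positive")
    y0 = cfg.y0_single
    if np.any(np.asarray(y) <= y0):
        raise ValueError("block frequency must exceed y0 = 1/(2 Ne)")
    log_ratio = np.log(y0) - np.log(y)  # negative
    edge = (cfg.delta_r / s) * log_ratio
    with np.errstate(divide="ignore"):
        term2 = np.where(edge < 0, np.log(-np.expm1(np.minimum(edge, -0.0))), -np.inf)
    ll = 2.0 * k_block * ((r / s) * log_ratio + term2)
    return float(ll) if ll.ndim == 0 else ll


def mcl_selection_arrays(r, y, k_block, cfg: ModelConfig, k_sample: int | None = None):
    """Vectorized closed-form estimates for many blocks at once.

    Returns (s_hat, log_cl, t_hat1, t_hat2, estimable).  Blocks with r = 0
    or y <= y0 are flagged non-estimable with s_hat = 0 (the r -> 0 limit
    of the estimator).  Fixed blocks (y = 1) are dated at
    y = 1 - 1/(2 k_sample), one sample chromosome short of fixation, which
    keeps the ages finite at the frequency resolution of the sample.
    """
    r, y, k_block = np.broadcast_arrays(
        np.atleast_1d(np.asarray(r, dtype=np.float64)),
        np.asarray(y, dtype=np.float64),
        np.asarray(k_block, dtype=np.float64),
    )
    y0 = cfg.y0_single
    dr = cfg.delta_r

    estimable = (r > 0) & (y > y0)
    s_hat = np.zeros_like(y)
    log_cl = np.full_like(y, -np.inf)
    t1 = np.full_like(y, np.inf)
    t2 = np.full_like(y, np.inf)

    if np.any(estimable):
        re = r[estimable]
        ye = y[estimable].copy()
        ke = k_block[estimable]
        if k_sample is None:
            k_sample = int(round(np.max(ke / ye)))
        ye[ye >= 1.0] = 1.0 - 1.0 / (2.0 * k_sample)
        log_y_ratio = np.log(y0) - np.log(ye)  # ln(y0/y) < 0
        denom = np.log(re) - np.log(dr + re)  # ln(r/(dr+r)) < 0
        se = dr / denom * log_y_ratio
        s_hat[estimable] = se
        log_cl[estimable] = log_composite_likelihood(se, re, ye, ke, cfg)
        t1[estimable] = sweep_age(se, ye, y0)
        t2e = np.full_like(se, np.inf)
        ok2 = ye > cfg.y0_pair
        if np.any(ok2):
            t2e[ok2] = sweep_age(se[ok2], ye[ok2], cfg.y0_pair)
        t2[estimable] = t2e
    return s_hat, log_cl, t1, t2, estimable


def mcl_selection(block, cfg: ModelConfig, k_sample: int | None = None) -> SelectionEstimate:
    """Closed-form MCL selection estimate for one annotated block.

    s_hat = dr / ln(r/(dr+r)) * ln(y0/y); degenerate blocks (r = 0 or
    y <= y0) yield the flagged zero estimate rather than an error.
    """
    s, ll, t1, t2, est = mcl_selection_arrays(
        block.r, block.y_freq, len(block.K), cfg, k_sample=k_sample
    )
    return SelectionEstimate(float(s[0]), float(ll[0]), float(t1[0]), float(t2[0]), bool(est[0]))
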