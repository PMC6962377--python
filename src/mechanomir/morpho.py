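"""Single-cell morphometrics: aspect-ratio statistics and mixture decomposition.

The aspect ratio (AR) of a cell is the major/minor axis ratio of its best-fit
ellipse; AR = 1 is a perfect circle and AR >= 2 is counted as elongated.  AR
distributions are modelled on the shifted variable x = AR - 1 as a 1- or
2-component lognormal mixture

    f(x) = sum_i  a_i / (x * sigma_i * sqrt(2 pi))
                 * exp(-(ln x - mu_i)^2 / (2 sigma_i^2)),

fit to a density-normalised histogram by least squares.  Each component peaks
at AR = exp(mu - sigma^2) + 1; the presence and location of a secondary peak
is what distinguishes an induced elongated subpopulation from a homogeneous
rounded one.  Between the 1- and 2-term fits, the one with the smaller SSE
(and correspondingly higher R^2) is selected, with a parsimony guard so that
a noise-level SSE reduction does not buy a second component.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import norm
from skimage.measure import regionprops

__all__ = [
    "CellShapeRecord",
    "ARHistogram",
    "LognormalComponent",
    "MixtureFit",
    "FitError",
    "measure_shapes",
    "percent_elongated",
    "ar_histogram",
    "fit_ar_pdf",
    "select_model",
    "component_mode",
    "flag_relevant_secondary",
]

ELONGATION_THRESHOLD = 2.0

#: Fixed histogram bin width in AR units; keeps SSE comparable across conditions.
DEFAULT_BIN_WIDTH = 0.1

#: Relative SSE improvement the 2-term fit must achieve to displace the 1-term
#: fit.  A genuine secondary population reduces SSE by far more; pure noise
#: fitting does not.
SSE_PARSIMONY_TOL = 0.05

#: The 2-term fit must cut SSE by more than this multiple of the histogram's
#: expected sampling-noise SSE to displace the 1-term fit.
NOISE_PENALTY_SCALE = 1.0

_SIGMA_BOUNDS = (0.01, 2.0)
_A_BOUNDS = (0.0, 2.0)
_N_MULTISTART = 5


class FitError(RuntimeError):
    """Mixture fit could not be performed or did not converge."""


@dataclass(frozen=True)
class CellShapeRecord:
    """One cell's shape measurement.

    ``excluded`` carries the exclusion reason: "edge" for cells cut by the
    image border, "dividing" for mitotic figures (an input flag; it cannot be
    inferred from a mask), or "none".
    """

    label: int
    ar: float
    area: float  # um^2
    excluded: str = "none"

    def __post_init__(self) -> None:
        if self.ar < 1.0:
            raise ValueError(f"aspect ratio must be >= 1, got {self.ar}")
        if self.excluded not in ("none", "edge", "dividing"):
            raise ValueError(f"unknown exclusion reason {self.excluded!r}")


@dataclass(frozen=True)
class ARHistogram:
    """Density-normalised aspect-ratio histogram."""

    bin_edges: np.ndarray
    densities: np.ndarray
    n: int

    def __post_init__(self) -> None:
        if len(self.densities) != len(self.bin_edges) - 1:
            raise ValueError("densities must have len(bin_edges) - 1 entries")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(self.densities < 0):
            raise ValueError("densities must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)


@dataclass(frozen=True)
class LognormalComponent:
    a: float
    mu: float
    sigma: float

    @property
    def mode(self) -> float:
        return component_mode(self.mu, self.sigma)


@dataclass(frozen=True)
class MixtureFit:
    """Fitted 1- or 2-term mixture, components ordered by ascending mode.

    ``noise_sse`` is the multinomial sampling-noise SSE expected for the
    fitted histogram, sum_j p_j (1 - p_j) / (n w^2); model selection uses it
    to tell a real SSE reduction from noise chasing.
    """

    components: tuple[LognormalComponent, ...]
    sse: float
    r2: float
    noise_sse: float | None = None
    warnings: tuple[str, ...] = field(default=(), compare=False)

    @property
    def n_terms(self) -> int:
        return len(self.components)

    @property
    def modes(self) -> tuple[float, ...]:
        return tuple(c.mode for c in self.components)


def component_mode(mu: float, sigma: float) -> float:
    """Peak AR of a shifted-lognormal component: exp(mu - sigma^2) + 1."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return math.exp(mu - sigma**2) + 1.0


def measure_shapes(
    label_mask: np.ndarray, pixel_size: float = 1.0
) -> list[CellShapeRecord]:
    """Measure aspect ratio and area for every labelled object in a mask.

    Parameters
    ----------
    label_mask : integer-labelled 2-D array, background 0.
    pixel_size : side of one pixel in micrometres; areas come back in um^2.

    Objects touching the image border are flagged ``excluded="edge"`` (they
    are incomplete cells); degenerate objects whose minor ellipse axis is zero
    (single-pixel rows/columns) are skipped.
    """
    mask = np.asarray(label_mask)
    if mask.ndim != 2:
        raise ValueError("label mask must be 2-D")
    h, w = mask.shape
    records: list[CellShapeRecord] = []
    for rp in regionprops(mask):
        minr, minc, maxr, maxc = rp.bbox
        on_edge = minr == 0 or minc == 0 or maxr == h or maxc == w
        if rp.axis_minor_length == 0:
            continue
        ar = rp.axis_major_length / rp.axis_minor_length
        records.append(
            CellShapeRecord(
                label=int(rp.label),
                ar=max(1.0, float(ar)),
                area=float(rp.area) * pixel_size**2,
                excluded="edge" if on_edge else "none",
            )
        )
    return records


def percent_elongated(
    shapes: Iterable[CellShapeRecord] | Sequence[float],
    threshold: float = ELONGATION_THRESHOLD,
) -> float:
    """Percentage of non-excluded cells with AR >= threshold.

    Accepts either CellShapeRecord iterables or bare AR sequences.
    """
    ars = [
        (s.ar if isinstance(s, CellShapeRecord) else float(s))
        for s in shapes
        if not (isinstance(s, CellShapeRecord) and s.excluded != "none")
    ]
    if not ars:
        raise ValueError("no non-excluded cells to summarise")
    ars = np.asarray(ars)
    return 100.0 * float(np.mean(ars >= threshold))


def ar_histogram(
    values: Sequence[float],
    bin_width: float = DEFAULT_BIN_WIDTH,
    upper_quantile: float = 0.995,
) -> ARHistogram:
    """Histogram AR values at fixed bin width over [1, upper quantile].

    Densities are normalised so they integrate to 1 over the binned support.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("no values to histogram")
    if np.any(vals < 1.0):
        raise ValueError("aspect ratios must be >= 1")
    upper = float(np.quantile(vals, upper_quantile))
    n_bins = max(1, int(math.ceil((upper - 1.0) / bin_width)))
    edges = 1.0 + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    total = counts.sum()
    if total == 0:
        raise ValueError("all values fall outside the binned support")
    densities = counts / (total * bin_width)
    return ARHistogram(bin_edges=edges, densities=densities, n=int(vals.size))


def _mixture_bin_density(
    params: np.ndarray, edges_x: np.ndarray, n_terms: int
) -> np.ndarray:
    """Model density per bin: component mass over the bin divided by width.

    Integrating the component over each bin (lognormal CDF differences)
    rather than evaluating the pdf at bin centres keeps the model well-posed
    for components much narrower than a bin, such as the near-degenerate
    secondary populations seen under intermediate compression.
    """
    widths = np.diff(edges_x)
    log_edges = np.log(np.maximum(edges_x, 1e-300))
    out = np.zeros(len(widths))
    for i in range(n_terms):
        a, mu, sigma = params[3 * i : 3 * i + 3]
        z = (log_edges - mu) / sigma
        out += a * np.diff(norm.cdf(z))
    return out / widths


def _weighted_moments_init(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Method-of-moments lognormal (mu, sigma) from weighted x samples."""
    w = w / w.sum()
    m = float(np.sum(w * x))
    v = float(np.sum(w * (x - m) ** 2))
    m = max(m, 1e-6)
    s2 = math.log1p(v / m**2) if v > 0 else 1e-3
    sigma = min(max(math.sqrt(s2), _SIGMA_BOUNDS[0] * 1.5), _SIGMA_BOUNDS[1] * 0.9)
    mu = math.log(m) - s2 / 2.0
    return mu, sigma


def _two_means_split(x: np.ndarray, w: np.ndarray) -> int:
    """Index of the best 1-D split of weighted points, by within-group SS.

    Exact weighted 2-means in one dimension: try every split position and
    pick the one minimising the total within-group weighted sum of squares.
    Returns the first index of the upper group.
    """
    best_j, best_ss = 1, np.inf
    for j in range(1, len(x)):
        ss = 0.0
        for sl in (slice(None, j), slice(j, None)):
            ws, xs = w[sl], x[sl]
            tw = ws.sum()
            if tw <= 0:
                continue
            m = np.sum(ws * xs) / tw
            ss += float(np.sum(ws * (xs - m) ** 2))
        if ss < best_ss:
            best_ss, best_j = ss, j
    return best_j


def _initial_params(hist: ARHistogram, n_terms: int) -> np.ndarray:
    centers_x = hist.centers - 1.0
    mass = hist.densities * hist.widths
    keep = (mass > 0) & (centers_x > 0)
    x, w = centers_x[keep], mass[keep]
    if x.size == 0:
        raise FitError("empty histogram after masking zero-mass bins")
    if n_terms == 1:
        mu, sigma = _weighted_moments_init(x, w)
        return np.array([w.sum(), mu, sigma])
    if x.size < 2:
        raise FitError("need at least two occupied bins for a 2-term fit")
    j = _two_means_split(np.log(x), w)
    params = []
    for sl in (slice(None, j), slice(j, None)):
        mu, sigma = _weighted_moments_init(x[sl], w[sl])
        params.extend([w[sl].sum(), mu, sigma])
    return np.array(params)


def _residual_peak_start(
    hist: ARHistogram, base1: np.ndarray, edges_x: np.ndarray
) -> np.ndarray | None:
    """Seed a second component at the largest positive 1-term residual.

    Narrow secondary populations (sigma well below the bin width) are
    invisible to a moment split of the pooled histogram but stick out of the
    1-term fit's residuals as a single-bin excess.
    """
    model = _mixture_bin_density(base1, edges_x, 1)
    resid = hist.densities - model
    j = int(np.argmax(resid))
    if resid[j] <= 0:
        return None
    x_peak = float(hist.centers[j] - 1.0)
    if x_peak <= 0:
        return None
    a2 = max(float(resid[j] * hist.widths[j]), 1e-3)
    sigma2 = 0.05
    return np.array(
        [max(base1[0] - a2, 1e-3), base1[1], base1[2],
         a2, math.log(x_peak) + sigma2**2, sigma2]
    )


def fit_ar_pdf(hist: ARHistogram, n_terms: int, seed: int = 0) -> MixtureFit:
    """Least-squares fit of the 1- or 2-term shifted-lognormal PDF.

    Parameters per term are (a, mu, sigma) with bounds a in [0, 2] and sigma
    in [0.01, 2].  Initialisation is method-of-moments (1-term) or an exact
    1-D weighted 2-means split of log(AR - 1) plus a residual-peak start
    (2-term), followed by five seeded, jittered multistarts; the best
    converged start wins.  SSE and R^2 are computed on the histogram
    densities.

    Raises
    ------
    FitError
        For degenerate histograms (< 8 bins, n < 50, or zero variance) or if
        no start converges.
    """
    if n_terms not in (1, 2):
        raise ValueError("n_terms must be 1 or 2")
    if len(hist.densities) < 8:
        raise FitError(f"need >= 8 bins, got {len(hist.densities)}")
    if hist.n < 50:
        raise FitError(f"need >= 50 observations, got {hist.n}")
    y = hist.densities
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot <= 0:
        raise FitError("zero-variance histogram (all mass in equal bins)")

    edges_x = hist.bin_edges - 1.0
    base = _initial_params(hist, n_terms)
    lo = np.tile([_A_BOUNDS[0], -10.0, _SIGMA_BOUNDS[0]], n_terms)
    hi = np.tile([_A_BOUNDS[1], 5.0, _SIGMA_BOUNDS[1]], n_terms)
    rng = np.random.default_rng(seed)

    def residuals(p: np.ndarray) -> np.ndarray:
        return _mixture_bin_density(p, edges_x, n_terms) - y

    starts: list[np.ndarray] = [base]
    if n_terms == 2:
        extra = _residual_peak_start(hist, _initial_params(hist, 1), edges_x)
        if extra is not None:
            starts.append(extra)
    while len(starts) < _N_MULTISTART + 1:
        jit = rng.normal(0.0, 0.15, size=base.shape)
        starts.append(base * (1.0 + jit))

    best = None
    for p0 in starts:
        p0 = np.clip(p0, lo + 1e-9, hi - 1e-9)
        try:
            res = least_squares(residuals, p0, bounds=(lo, hi), method="trf")
        except Exception:  # singular Jacobian etc.; try the next start
            continue
        if not res.success:
            continue
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[0]:
            best = (sse, res.x)
    if best is None:
        raise FitError(f"no converged start among {_N_MULTISTART} for {n_terms}-term fit")

    sse, p = best
    bin_probs = y * hist.widths
    noise_sse = float(
        np.sum(bin_probs * (1.0 - bin_probs)) / (hist.n * hist.widths[0] ** 2)
    )
    comps = sorted(
        (
            LognormalComponent(a=float(p[3 * i]), mu=float(p[3 * i + 1]),
                               sigma=float(p[3 * i + 2]))
            for i in range(n_terms)
        ),
        key=lambda c: c.mode,
    )
    r2 = 1.0 - sse / sstot
    return MixtureFit(components=tuple(comps), sse=sse, r2=r2, noise_sse=noise_sse)


def select_model(
    fit1: MixtureFit,
    fit2: MixtureFit,
    rel_tol: float = SSE_PARSIMONY_TOL,
    min_mode_separation: float = DEFAULT_BIN_WIDTH,
    noise_penalty: float = NOISE_PENALTY_SCALE,
) -> MixtureFit:
    """Choose between the 1- and 2-term fits of the same histogram.

    The fit with the smaller SSE wins, subject to parsimony guards that keep
    a noise-chasing second component from displacing the simpler model:

    * the SSE reduction must exceed ``noise_penalty`` times the histogram's
      expected sampling-noise SSE (and, as a floor, ``rel_tol`` of the
      1-term SSE) -- with nested models extra parameters always shave some
      SSE off, and on a finite sample the shave can reach the noise level;
    * the two modes must be separated by at least ``min_mode_separation``
      (one bin width by default) -- components closer than the histogram
      resolution are not identifiable as two populations.

    If the raw SSE and R^2 rankings ever disagree (possible only when the
    fits were scored against different histograms), SSE governs and a
    warning is recorded.
    """
    separated = (fit2.modes[-1] - fit2.modes[0]) >= min_mode_separation
    penalty = rel_tol * fit1.sse
    if fit1.noise_sse is not None:
        penalty = max(penalty, noise_penalty * fit1.noise_sse)
    sse_prefers_2 = (fit1.sse - fit2.sse) > penalty and separated
    raw_sse_prefers_2 = fit2.sse < fit1.sse
    r2_prefers_2 = fit2.r2 > fit1.r2
    chosen = fit2 if sse_prefers_2 else fit1
    if raw_sse_prefers_2 != r2_prefers_2 and fit2.sse != fit1.sse:
        msg = (
            "SSE and R^2 rankings disagree "
            f"(sse: {fit1.sse:.4g} vs {fit2.sse:.4g}, "
            f"r2: {fit1.r2:.4g} vs {fit2.r2:.4g}); SSE governs"
        )
        warnings.warn(msg, stacklevel=2)
        chosen = MixtureFit(
            components=chosen.components,
            sse=chosen.sse,
            r2=chosen.r2,
            warnings=chosen.warnings + (msg,),
        )
    return chosen


def flag_relevant_secondary(
    fit: MixtureFit, threshold: float = ELONGATION_THRESHOLD
) -> bool:
    """Whether the selected fit has a secondary peak in the elongated range.

    A 2-term fit whose secondary mode still falls below AR = 2 describes two
    rounded subpopulations, not an elongated one.
    """
    return fit.n_terms == 2 and fit.modes[-1] >= threshold
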