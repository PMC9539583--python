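"""Multi-SNR numerical phantom simulator.

Generates Shepp–Logan-style 64x64 phantoms with six elliptical regions of
interest (ROIs).  Each ROI carries a single uniformly drawn (D, f, D*)
triplet and its own b0 (proton-density-like) level; the multi-b
diffusion-weighted stack is built from the biexponential model and
corrupted with Rician noise whose Gaussian scale is set voxel-wise so that
every foreground voxel sees the same SNR (sigma = S0 / SNR).

Background voxels hold no signal (pure Rician noise floor) and are excluded
from training and evaluation everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AcquisitionScheme, IVIMParams, ParamRanges, signal_vector

__all__ = [
    "SHEPP_LOGAN_ELLIPSES",
    "PhantomTemplate",
    "PhantomInstance",
    "SimulationGrid",
    "sample_roi_params",
    "add_rician_noise",
    "generate_phantom",
    "generate_grid",
]

#: Six-region elliptical layout in normalized [-1, 1]^2 coordinates:
#: (cx, cy, semi_axis_x, semi_axis_y, rotation_deg).  The first ellipse is
#: the head outline; its interior minus the five inner ellipses is region 1,
#: the inner ellipses are regions 2..6.  The inner ellipses are mutually
#: disjoint by construction (checked in the test suite).
SHEPP_LOGAN_ELLIPSES: tuple[tuple[float, float, float, float, float], ...] = (
    (0.00, 0.00, 0.72, 0.95, 0.0),    # head -> region 1 (minus the rest)
    (-0.30, 0.20, 0.16, 0.35, 15.0),  # left "ventricle"  -> region 2
    (0.30, 0.20, 0.16, 0.35, -15.0),  # right "ventricle" -> region 3
    (0.00, -0.35, 0.35, 0.18, 0.0),   # inferior lobe     -> region 4
    (0.00, 0.62, 0.25, 0.12, 0.0),    # superior strip    -> region 5
    (0.00, 0.10, 0.095, 0.095, 0.0),  # central nodule    -> region 6
)

N_ROIS = 6


def _ellipse_mask(shape: tuple[int, int], cx, cy, ax, ay, theta_deg) -> np.ndarray:
    ny, nx = shape
    # pixel centres on a [-1, 1] grid; y grows upward to match the layout
    xs = (np.arange(nx) + 0.5) / nx * 2.0 - 1.0
    ys = 1.0 - (np.arange(ny) + 0.5) / ny * 2.0
    X, Y = np.meshgrid(xs, ys)
    t = np.deg2rad(theta_deg)
    Xr = (X - cx) * np.cos(t) + (Y - cy) * np.sin(t)
    Yr = -(X - cx) * np.sin(t) + (Y - cy) * np.cos(t)
    return (Xr / ax) ** 2 + (Yr / ay) ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomTemplate:
    """Integer ROI label map (0 = background, 1..6 = regions) plus geometry."""

    shape: tuple[int, int]
    roi_labels: np.ndarray
    roi_geometry: tuple[tuple[float, float, float, float, float], ...]

    @classmethod
    def build(cls, shape: tuple[int, int] = (64, 64),
              ellipses=SHEPP_LOGAN_ELLIPSES) -> "PhantomTemplate":
        head, inner = ellipses[0], ellipses[1:]
        labels = np.zeros(shape, dtype=np.int16)
        head_mask = _ellipse_mask(shape, *head)
        labels[head_mask] = 1
        for k, ell in enumerate(inner, start=2):
            mask = _ellipse_mask(shape, *ell) & head_mask
            labels[mask] = k
        present = np.unique(labels)
        if not np.array_equal(present, np.arange(N_ROIS + 1)):
            raise ValueError(f"template does not realize 6 ROIs: labels {present}")
        labels.setflags(write=False)
        return cls(shape=shape, roi_labels=labels, roi_geometry=ellipses)

    @property
    def foreground(self) -> np.ndarray:
        return self.roi_labels > 0


@dataclass
class PhantomInstance:
    """One simulated multi-b phantom with its ground truth.

    ``noiseless`` and ``noisy`` have shape ``(rows, cols, n_b)``; ground-truth
    maps and ``b0_map`` are ``(rows, cols)`` with zeros on background.
    ``noise_sigma`` is the per-voxel Gaussian scale actually applied, kept so
    the SNR-homogeneity contract is auditable.
    """

    noiseless: np.ndarray
    noisy: np.ndarray
    truth_D: np.ndarray
    truth_f: np.ndarray
    truth_Dstar: np.ndarray
    b0_map: np.ndarray
    noise_sigma: np.ndarray
    roi_labels: np.ndarray
    snr: float
    seed: object
    roi_params: dict = field(default_factory=dict)
    roi_b0: dict = field(default_factory=dict)

    @property
    def foreground(self) -> np.ndarray:
        return self.roi_labels > 0

    def truth_array(self) -> np.ndarray:
        """Ground truth stacked as ``(rows, cols, 3)`` ordered (D, f, D*)."""
        return np.stack([self.truth_D, self.truth_f, self.truth_Dstar], axis=-1)


@dataclass(frozen=True)
class SimulationGrid:
    """Simulation campaign layout: SNR levels x phantom counts.

    The first half of each SNR's phantoms is tagged ``train``, the second
    half ``test``.
    """

    snr_levels: tuple[float, ...] = (10, 15, 20, 25, 50, 75, 100)
    phantoms_per_snr: int = 2000
    master_seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.snr_levels):
            raise ValueError("SNR levels must be positive")
        if self.phantoms_per_snr <= 0:
            raise ValueError("phantoms_per_snr must be positive")


def sample_roi_params(ranges: ParamRanges, rng: np.random.Generator) -> IVIMParams:
    """Draw one (D, f, D*) triplet, each component uniform over its range."""
    return IVIMParams(
        D=rng.uniform(*ranges.D),
        f=rng.uniform(*ranges.f),
        Dstar=rng.uniform(*ranges.Dstar),
    )


def add_rician_noise(noiseless: np.ndarray, snr: float, reference: np.ndarray,
                     rng: np.random.Generator,
                     variance_mode: bool = False) -> np.ndarray:
    """Corrupt a magnitude signal with Rician noise at a per-voxel SNR.

    Each sample becomes ``sqrt((S + g1)^2 + g2^2)`` with ``g1, g2`` i.i.d.
    zero-mean Gaussians of standard deviation ``reference / snr`` (the
    conventional magnitude-MRI SNR definition).  ``reference`` broadcasts
    against ``noiseless`` (trailing b-axis allowed), so a per-voxel b0 map
    yields the same SNR at every voxel regardless of its b0 level.

    With ``variance_mode=True`` the Gaussian *variance* is ``reference/snr``
    instead (the literal alternative reading of noise scaled by 1/SNR).
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    noiseless = np.asarray(noiseless, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if reference.ndim == noiseless.ndim - 1:
        reference = reference[..., None]
    sigma = np.sqrt(reference / snr) if variance_mode else reference / snr
    g1 = rng.standard_normal(noiseless.shape)
    g2 = rng.standard_normal(noiseless.shape)
    return np.hypot(noiseless + sigma * g1, sigma * g2)


def generate_phantom(template: PhantomTemplate, scheme: AcquisitionScheme,
                     ranges: ParamRanges, snr: float, rng: np.random.Generator,
                     b0_range: tuple[float, float] = (0.5, 1.5)) -> PhantomInstance:
    """Build one phantom: per-ROI triplets and b0 levels, then Rician noise.

    The noise scale is ``b0 / snr`` voxel-wise on foreground; background
    (zero signal) receives pure noise at the median foreground scale so the
    image has a realistic noise floor.
    """
    labels = template.roi_labels
    shape = template.shape
    n_b = scheme.n_b

    noiseless = np.zeros(shape + (n_b,))
    truth = np.zeros(shape + (3,))
    b0_map = np.zeros(shape)
    roi_params: dict[int, IVIMParams] = {}
    roi_b0: dict[int, float] = {}
    for label in range(1, N_ROIS + 1):
        params = sample_roi_params(ranges, rng)
        b0 = float(rng.uniform(*b0_range))
        mask = labels == label
        noiseless[mask] = signal_vector(params, scheme, S0=b0)
        truth[mask] = params.as_array()
        b0_map[mask] = b0
        roi_params[label] = params
        roi_b0[label] = b0

    sigma = np.where(labels > 0, b0_map, np.median(b0_map[labels > 0])) / snr
    noisy = add_rician_noise(noiseless, snr, sigma * snr, rng)

    return PhantomInstance(
        noiseless=noiseless, noisy=noisy,
        truth_D=truth[..., 0], truth_f=truth[..., 1], truth_Dstar=truth[..., 2],
        b0_map=b0_map, noise_sigma=sigma, roi_labels=labels.copy(),
        snr=float(snr), seed=None, roi_params=roi_params, roi_b0=roi_b0,
    )


def _phantom_rng(master_seed: int, snr_index: int, phantom_index: int):
    """Counter-based per-phantom seeding: reproducible and order-independent."""
    key = (master_seed, snr_index, phantom_index)
    return np.random.default_rng(np.random.SeedSequence(key)), key


def generate_grid(grid: SimulationGrid,
                  template: PhantomTemplate | None = None,
                  scheme: AcquisitionScheme | None = None,
                  ranges: ParamRanges | None = None,
                  split: str | None = None):
    """Yield ``(split_tag, phantom)`` pairs over the whole simulation grid.

    ``split`` restricts the iterator to ``"train"`` (first half of each SNR)
    or ``"test"`` (second half).  Phantom seeds derive from
    ``grid.master_seed`` by a counter scheme, so any sub-range regenerates
    identically.
    """
    template = template or PhantomTemplate.build()
    scheme = scheme or AcquisitionScheme()
    ranges = ranges or ParamRanges()
    n_train = grid.phantoms_per_snr // 2
    for si, snr in enumerate(grid.snr_levels):
        for pi in range(grid.phantoms_per_snr):
            tag = "train" if pi < n_train else "test"
            if split is not None and tag != split:
                continue
            rng, key = _phantom_rng(grid.master_seed, si, pi)
            inst = generate_phantom(template, scheme, ranges, snr, rng)
            inst.seed = key
            yield tag, inst
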