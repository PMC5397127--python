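"""Synthetic brain phantoms and multi-echo FLASH signal simulation.

A phantom is a labelled 3D grid (background, CSF, cortical grey matter,
white matter, striatal grey matter) in which every voxel carries the
quantitative tissue parameters A (signal amplitude), R1 (longitudinal
relaxation rate), R2* (effective transverse relaxation rate) and the MT
saturation fraction delta.  Three spoiled-gradient-echo acquisitions
(PD-weighted, T1-weighted, MT-weighted) are simulated from those fields,
and whole cohorts with group differences in striatal volume and striatal
"iron" (R2* with a coupled R1 increase) can be generated for downstream
map fitting, segmentation and group statistics.

Internal units are SI throughout: seconds, radians, rates in 1/s.  The
configuration layer accepts milliseconds and degrees and converts on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

__all__ = [
    "AcquisitionProtocol",
    "TissueParams",
    "PhantomSpec",
    "CohortSpec",
    "Phantom",
    "MultiEchoVolume",
    "SimulatedSubject",
    "PDW_PROTOCOL",
    "T1W_PROTOCOL",
    "MTW_PROTOCOL",
    "DEFAULT_PROTOCOLS",
    "CovariateDist",
    "DEFAULT_TISSUES",
    "flash_signal",
    "ernst_signal",
    "make_phantom",
    "simulate_acquisition",
    "simulate_cohort",
    "noise_scale",
]

# Label values used in the phantom label volume.
BACKGROUND, CSF, CORTICAL_GM, WM, STRIATAL_GM = 0, 1, 2, 3, 4

LABEL_NAMES = {
    BACKGROUND: "background",
    CSF: "csf",
    CORTICAL_GM: "cortical_gm",
    WM: "wm",
    STRIATAL_GM: "striatal_gm",
}


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Sequence parameters of one spoiled multi-echo FLASH contrast.

    Parameters
    ----------
    name : str
        Contrast label, one of ``"pdw"``, ``"t1w"``, ``"mtw"``.
    tr : float
        Repetition time in seconds.
    flip_angle : float
        Excitation flip angle in radians.
    echo_times : tuple of float
        Strictly increasing echo times in seconds, all shorter than ``tr``.
    mt_on : bool
        Whether the off-resonance magnetization-transfer pulse is applied.
        Only the MT-weighted contrast runs with MT on.
    """

    name: str
    tr: float
    flip_angle: float
    echo_times: tuple[float, ...]
    mt_on: bool = False

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if not 0 < self.flip_angle < math.pi / 2:
            raise ValueError(
                f"flip_angle must lie in (0, pi/2) radians, got {self.flip_angle}"
            )
        te = np.asarray(self.echo_times, dtype=float)
        if te.size == 0:
            raise ValueError("echo_times must be non-empty")
        if np.any(np.diff(te) <= 0):
            raise ValueError("echo_times must be strictly increasing")
        if te[-1] >= self.tr:
            raise ValueError("all echo times must be shorter than tr")
        if self.mt_on and self.name != "mtw":
            raise ValueError("mt_on is only valid for the mtw protocol")
        object.__setattr__(self, "echo_times", tuple(float(t) for t in te))

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times)

    @classmethod
    def from_clinical_units(
        cls,
        name: str,
        tr_ms: float,
        flip_angle_deg: float,
        echo_times_ms,
        mt_on: bool = False,
    ) -> "AcquisitionProtocol":
        """Build a protocol from the units printed on scanner consoles."""
        return cls(
            name=name,
            tr=tr_ms * 1e-3,
            flip_angle=math.radians(flip_angle_deg),
            echo_times=tuple(t * 1e-3 for t in echo_times_ms),
            mt_on=mt_on,
        )


def _equidistant_echoes(first_ms: float, last_ms: float, n: int) -> tuple[float, ...]:
    return tuple(np.linspace(first_ms, last_ms, n))


# The three-contrast multi-echo FLASH protocol of the study this package
# emulates (1.5 T multi-parameter mapping): PDw TR 24 ms / 6 deg / 8 echoes
# 2.51-21.9 ms; T1w TR 19 ms / 20 deg / 4 echoes 2.51-10.82 ms; MTw TR 30 ms
# / 12 deg / the same 4 echoes with the MT pulse on.
PDW_PROTOCOL = AcquisitionProtocol.from_clinical_units(
    "pdw", tr_ms=24.0, flip_angle_deg=6.0, echo_times_ms=_equidistant_echoes(2.51, 21.9, 8)
)
T1W_PROTOCOL = AcquisitionProtocol.from_clinical_units(
    "t1w", tr_ms=19.0, flip_angle_deg=20.0, echo_times_ms=_equidistant_echoes(2.51, 10.82, 4)
)
MTW_PROTOCOL = AcquisitionProtocol.from_clinical_units(
    "mtw", tr_ms=30.0, flip_angle_deg=12.0, echo_times_ms=_equidistant_echoes(2.51, 10.82, 4),
    mt_on=True,
)

DEFAULT_PROTOCOLS = {"pdw": PDW_PROTOCOL, "t1w": T1W_PROTOCOL, "mtw": MTW_PROTOCOL}


@dataclass(frozen=True)
class TissueParams:
    """Quantitative parameters of one tissue class.

    Attributes
    ----------
    amplitude : float
        Signal amplitude A at TE=0 per unit flip-angle response
        (arbitrary units, proportional to proton density), > 0.
    r1 : float
        Longitudinal relaxation rate R1 = 1/T1 in 1/s, > 0.
    r2star : float
        Effective transverse relaxation rate R2* in 1/s, >= 0.
    mtsat : float
        MT saturation per TR (delta), a dimensionless fraction in [0, 1).
    """

    amplitude: float
    r1: float
    r2star: float
    mtsat: float

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.r1 <= 0:
            raise ValueError("r1 must be > 0")
        if self.r2star < 0:
            raise ValueError("r2star must be >= 0")
        if not 0 <= self.mtsat < 1:
            raise ValueError("mtsat must lie in [0, 1)")


# Default 1.5 T tissue parameters.  Amplitudes follow relative proton
# density (CSF > GM > WM); R1 values correspond to T1 of roughly 4 s
# (CSF), 1.1 s (GM) and 0.63 s (WM); striatal grey matter shares the
# cortical-GM parameters except for its R2*, which sits at the control-group
# ventral-striatum value of 13.26 1/s.  MT saturation is essentially absent
# in CSF, intermediate in GM and highest in myelin-rich WM.
DEFAULT_TISSUES: dict[str, TissueParams] = {
    "background": TissueParams(amplitude=1.0, r1=1.0, r2star=1.0, mtsat=0.0),
    "csf": TissueParams(amplitude=1000.0, r1=0.25, r2star=1.0, mtsat=0.002),
    "cortical_gm": TissueParams(amplitude=800.0, r1=0.90, r2star=12.0, mtsat=0.02),
    "wm": TissueParams(amplitude=700.0, r1=1.60, r2star=16.0, mtsat=0.035),
    "striatal_gm": TissueParams(amplitude=800.0, r1=0.90, r2star=13.26, mtsat=0.02),
}

_LABEL_TO_TISSUE = {
    BACKGROUND: "background",
    CSF: "csf",
    CORTICAL_GM: "cortical_gm",
    WM: "wm",
    STRIATAL_GM: "striatal_gm",
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue table of a spherical brain-like phantom.

    The phantom is a brain sphere of ``brain_radius_mm`` containing a
    central CSF "ventricle" sphere, a cortical grey-matter ribbon of
    ``gm_thickness_mm`` at its surface, white matter in between, and two
    striatal grey-matter spheres embedded in the white matter.  An optional
    cortical patch models focal cortical atrophy (the parietal analogue of
    the striatal effect): inside a sphere of ``cortical_patch_radius_mm``
    around ``cortical_patch_center_mm`` the outer part of the GM ribbon is
    replaced by CSF, thinning the ribbon by ``cortical_atrophy_fraction``.

    ``striatal_r1_shift`` moves striatal R1 from the cortical-GM value
    toward the WM value (0 = GM-like, 1 = WM-like) and models the
    T1-shortening effect of striatal iron.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: float = 1.25
    brain_radius_mm: float = 27.0
    csf_radius_mm: float = 5.0
    gm_thickness_mm: float = 4.0
    striatum_radius_mm: float = 5.0
    striatum_offset_mm: float = 11.0
    tissues: dict[str, TissueParams] = field(default_factory=lambda: dict(DEFAULT_TISSUES))
    striatal_r1_shift: float = 0.0
    cortical_atrophy_fraction: float = 0.0
    cortical_patch_radius_mm: float = 8.0
    cortical_patch_center_mm: tuple[float, float, float] | None = None
    center_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s < 8 for s in self.grid_shape):
            raise ValueError("grid_shape must be at least 8 voxels per axis")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.striatum_radius_mm < 0:
            raise ValueError("striatum_radius_mm must be >= 0")
        if not 0 <= self.cortical_atrophy_fraction < 1:
            raise ValueError("cortical_atrophy_fraction must lie in [0, 1)")
        if not 0 <= self.striatal_r1_shift <= 1:
            raise ValueError("striatal_r1_shift must lie in [0, 1]")
        missing = set(_LABEL_TO_TISSUE.values()) - set(self.tissues)
        if missing:
            raise ValueError(f"tissue table missing classes: {sorted(missing)}")
        half_extent = min(self.grid_shape) * self.voxel_size_mm / 2
        if self.brain_radius_mm >= half_extent:
            raise ValueError("brain sphere does not fit inside the grid")
        # The striatal spheres must stay inside WM: clear of the CSF core
        # and of the GM ribbon.
        if self.striatum_radius_mm > 0:
            inner = self.striatum_offset_mm - self.striatum_radius_mm
            outer = self.striatum_offset_mm + self.striatum_radius_mm
            if inner < self.csf_radius_mm:
                raise ValueError("striatum overlaps the CSF core")
            if outer > self.brain_radius_mm - self.gm_thickness_mm:
                raise ValueError("striatum extends beyond the white matter")

    @classmethod
    def fit_grid(
        cls,
        grid_shape: tuple[int, int, int],
        voxel_size_mm: float = 1.25,
        **overrides,
    ) -> "PhantomSpec":
        """Default geometry scaled proportionally to fit a given grid."""
        factor = min(grid_shape) * voxel_size_mm / (48 * 1.25)
        scaled = dict(
            grid_shape=tuple(grid_shape),
            voxel_size_mm=voxel_size_mm,
            brain_radius_mm=27.0 * factor,
            csf_radius_mm=5.0 * factor,
            gm_thickness_mm=4.0 * factor,
            striatum_radius_mm=5.0 * factor,
            striatum_offset_mm=11.0 * factor,
            cortical_patch_radius_mm=8.0 * factor,
        )
        scaled.update(overrides)
        return cls(**scaled)

    @classmethod
    def small(cls, **overrides) -> "PhantomSpec":
        """Scaled-down 32-cube phantom for permutation-heavy experiments."""
        defaults = dict(
            grid_shape=(32, 32, 32),
            voxel_size_mm=1.25,
            brain_radius_mm=17.0,
            csf_radius_mm=4.0,
            gm_thickness_mm=3.0,
            striatum_radius_mm=3.0,
            striatum_offset_mm=8.0,
            cortical_patch_radius_mm=6.0,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def effective_tissues(self) -> dict[str, TissueParams]:
        """Tissue table with the striatal R1 iron shift applied."""
        tissues = dict(self.tissues)
        if self.striatal_r1_shift > 0:
            gm_r1 = tissues["cortical_gm"].r1
            wm_r1 = tissues["wm"].r1
            stri = tissues["striatal_gm"]
            tissues["striatal_gm"] = replace(
                stri, r1=stri.r1 + self.striatal_r1_shift * (wm_r1 - gm_r1)
            )
        return tissues

    def analytic_gm_volume_mm3(self) -> float:
        """Analytic volume of all grey matter (ribbon + striatal spheres)."""
        r_out = self.brain_radius_mm
        r_in = self.brain_radius_mm - self.gm_thickness_mm
        shell = 4 / 3 * math.pi * (r_out**3 - r_in**3)
        spheres = 2 * 4 / 3 * math.pi * self.striatum_radius_mm**3
        return shell + spheres


@dataclass
class Phantom:
    """A realized phantom: label volume plus voxelwise parameter fields."""

    spec: PhantomSpec
    labels: np.ndarray  # int, 3D
    fields: dict[str, np.ndarray]  # keys a, r1, r2star, mtsat; 3D float
    brain_mask: np.ndarray  # bool, 3D
    gm_mask: np.ndarray  # bool: cortical + striatal GM
    striatal_mask: np.ndarray  # bool
    wm_mask: np.ndarray  # bool

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spec.voxel_size_mm**3


def _radial_grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nx, ny, nz = spec.grid_shape
    center = (np.array(spec.grid_shape) - 1) / 2.0 * spec.voxel_size_mm
    off = np.asarray(spec.center_offset_mm, dtype=float)
    x = np.arange(nx) * spec.voxel_size_mm - center[0] - off[0]
    y = np.arange(ny) * spec.voxel_size_mm - center[1] - off[1]
    z = np.arange(nz) * spec.voxel_size_mm - center[2] - off[2]
    return np.meshgrid(x, y, z, indexing="ij")


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterize a :class:`PhantomSpec` into labels and parameter fields.

    Deterministic given the spec.  Every voxel carries the
    :class:`TissueParams` of its label; ground-truth brain, grey-matter and
    striatal masks are returned alongside.
    """
    xg, yg, zg = _radial_grids(spec)
    r = np.sqrt(xg**2 + yg**2 + zg**2)

    labels = np.full(spec.grid_shape, BACKGROUND, dtype=np.int16)
    labels[r <= spec.brain_radius_mm] = CORTICAL_GM
    labels[r <= spec.brain_radius_mm - spec.gm_thickness_mm] = WM
    labels[r <= spec.csf_radius_mm] = CSF

    if spec.cortical_atrophy_fraction > 0:
        if spec.cortical_patch_center_mm is None:
            # Default patch sits on top of the brain, mid-ribbon on +z.
            mid = spec.brain_radius_mm - spec.gm_thickness_mm / 2
            cx, cy, cz = 0.0, 0.0, mid
        else:
            cx, cy, cz = spec.cortical_patch_center_mm
        d_patch = np.sqrt((xg - cx) ** 2 + (yg - cy) ** 2 + (zg - cz) ** 2)
        receded = spec.brain_radius_mm - spec.gm_thickness_mm * spec.cortical_atrophy_fraction
        thin = (d_patch <= spec.cortical_patch_radius_mm) & (labels == CORTICAL_GM) & (r > receded)
        labels[thin] = BACKGROUND

    if spec.striatum_radius_mm > 0:
        for sign in (-1.0, 1.0):
            d = np.sqrt((xg - sign * spec.striatum_offset_mm) ** 2 + yg**2 + zg**2)
            labels[d <= spec.striatum_radius_mm] = STRIATAL_GM

    tissues = spec.effective_tissues()
    fields = {k: np.empty(spec.grid_shape, dtype=np.float64) for k in ("a", "r1", "r2star", "mtsat")}
    for label, tname in _LABEL_TO_TISSUE.items():
        m = labels == label
        tp = tissues[tname]
        fields["a"][m] = tp.amplitude
        fields["r1"][m] = tp.r1
        fields["r2star"][m] = tp.r2star
        fields["mtsat"][m] = tp.mtsat

    return Phantom(
        spec=spec,
        labels=labels,
        fields=fields,
        brain_mask=labels != BACKGROUND,
        gm_mask=(labels == CORTICAL_GM) | (labels == STRIATAL_GM),
        striatal_mask=labels == STRIATAL_GM,
        wm_mask=labels == WM,
    )


def flash_signal(
    amplitude, r1, r2star, mtsat, protocol: AcquisitionProtocol, te
) -> np.ndarray:
    """Spoiled gradient-echo signal under the rational small-angle model.

    S(TE) = A * alpha * R1 * TR / (R1*TR + alpha^2/2 + delta) * exp(-TE*R2*)

    where delta is the per-TR MT saturation fraction, applied only when the
    protocol runs with the MT pulse on.  This is the exact algebraic inverse
    of the MT-saturation estimator delta = (A*alpha/S - 1)*R1*TR - alpha^2/2,
    so noiseless simulation and map fitting round-trip exactly.

    All inputs broadcast; scalars in, scalar out.
    """
    amplitude = np.asarray(amplitude, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    r2star = np.asarray(r2star, dtype=float)
    delta = np.asarray(mtsat, dtype=float) if protocol.mt_on else 0.0
    te = np.asarray(te, dtype=float)
    alpha, tr = protocol.flip_angle, protocol.tr
    s0 = amplitude * alpha * r1 * tr / (r1 * tr + alpha**2 / 2 + delta)
    out = s0 * np.exp(-te * r2star)
    return out if out.ndim else float(out)


def ernst_signal(amplitude, r1, r2star, protocol: AcquisitionProtocol, te) -> np.ndarray:
    """Full Ernst-equation spoiled gradient-echo signal (no MT term).

    S(TE) = A * sin(a) * (1 - E1) / (1 - cos(a)*E1) * exp(-TE*R2*),
    E1 = exp(-TR*R1).  Provided for the MT-free contrasts only, to quantify
    the bias of the rational small-angle model used everywhere else.
    """
    if protocol.mt_on:
        raise ValueError("ernst_signal is defined only for MT-off protocols")
    amplitude = np.asarray(amplitude, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    r2star = np.asarray(r2star, dtype=float)
    te = np.asarray(te, dtype=float)
    a = protocol.flip_angle
    e1 = np.exp(-protocol.tr * r1)
    s0 = amplitude * math.sin(a) * (1 - e1) / (1 - math.cos(a) * e1)
    out = s0 * np.exp(-te * r2star)
    return out if out.ndim else float(out)


@dataclass
class MultiEchoVolume:
    """4D signal (x, y, z, echo) for one contrast, with its protocol."""

    data: np.ndarray
    protocol: AcquisitionProtocol
    voxel_size_mm: float = 1.25

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, echo)")
        if self.data.shape[3] != self.protocol.n_echoes:
            raise ValueError(
                f"4th dimension ({self.data.shape[3]}) must equal the number of "
                f"echo times ({self.protocol.n_echoes})"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("signal values must be finite")


def _forward_4d(fields: dict[str, np.ndarray], protocol: AcquisitionProtocol) -> np.ndarray:
    te = np.asarray(protocol.echo_times)
    return flash_signal(
        fields["a"][..., None],
        fields["r1"][..., None],
        fields["r2star"][..., None],
        fields["mtsat"][..., None],
        protocol,
        te[None, None, None, :],
    )


def noise_scale(
    fields: dict[str, np.ndarray],
    wm_mask: np.ndarray,
    reference_protocol: AcquisitionProtocol = PDW_PROTOCOL,
) -> float:
    """Absolute noise unit: mean noiseless first-echo WM signal of the
    reference (PD-weighted) contrast.  ``noise_sigma`` values are fractions
    of this quantity."""
    te0 = reference_protocol.echo_times[0]
    s = flash_signal(
        fields["a"][wm_mask],
        fields["r1"][wm_mask],
        fields["r2star"][wm_mask],
        fields["mtsat"][wm_mask],
        reference_protocol,
        te0,
    )
    return float(np.mean(s))


def simulate_acquisition(
    fields: dict[str, np.ndarray],
    protocol: AcquisitionProtocol,
    noise_sigma: float = 0.0,
    seed: int | np.random.Generator | None = None,
    wm_mask: np.ndarray | None = None,
    voxel_size_mm: float = 1.25,
) -> MultiEchoVolume:
    """Simulate one multi-echo acquisition from voxelwise parameter fields.

    Additive zero-mean Gaussian noise with standard deviation
    ``noise_sigma * noise_scale(fields, wm_mask)`` is applied to every echo.
    ``noise_sigma=0`` returns exactly the noiseless forward model and the
    result is reproducible given the seed.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    data = _forward_4d(fields, protocol)
    if noise_sigma > 0:
        if wm_mask is None:
            raise ValueError("wm_mask is required to scale the noise when noise_sigma > 0")
        rng = np.random.default_rng(seed)
        sd = noise_sigma * noise_scale(fields, wm_mask)
        data = data + rng.normal(0.0, sd, size=data.shape)
    return MultiEchoVolume(data=data, protocol=protocol, voxel_size_mm=voxel_size_mm)


@dataclass(frozen=True)
class CovariateDist:
    """Normal distribution of one covariate, per group."""

    mean: float
    sd: float


# Cohort covariate distributions mirror the study demographics: two groups
# of 30, matched for age, with higher depression (BDI) and trait anxiety
# (STAI) scores in patients; months on stimulant medication apply to the
# patient group only.  Total intracranial volume is not reported there and
# uses a typical adult distribution.
DEFAULT_COVARIATES: dict[str, dict[str, CovariateDist]] = {
    "age": {"patient": CovariateDist(33.7, 9.51), "control": CovariateDist(32.6, 9.54)},
    "bdi": {"patient": CovariateDist(13.7, 8.57), "control": CovariateDist(5.6, 6.57)},
    "stai": {"patient": CovariateDist(53.5, 11.04), "control": CovariateDist(36.5, 10.71)},
    "tiv": {"patient": CovariateDist(1450.0, 130.0), "control": CovariateDist(1450.0, 130.0)},
    "med_months": {"patient": CovariateDist(32.7, 39.58), "control": CovariateDist(0.0, 0.0)},
}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level design of a simulated two-group study.

    Group effects applied to patients:

    - ``atrophy_fraction``: fractional reduction of the striatal sphere
      radius (striatal grey-matter atrophy).
    - ``delta_r2star``: additive striatal R2* increase in 1/s (iron load);
      the study's group difference 14.20 - 13.26 = 0.94 1/s is the default.
    - ``iron_r1_slope``: additive striatal R1 increase per unit of R2*
      increase (dimensionless, both rates in 1/s), modelling the
      T1-shortening that accompanies iron deposition.
    - ``cortical_atrophy_fraction``: focal cortical ribbon thinning in the
      parietal-analogue patch (iron-free comparison effect).

    Subject-level striatal iron varies around the group baseline:
    ``r2star_subject_sd`` (1/s) is the between-subject SD of striatal R2*,
    and ``age_r2star_slope`` (1/s per year) couples striatal iron to age,
    reproducing the positive age-iron association seen in vivo.  Both
    deviations also raise R1 through ``iron_r1_slope``.  Setting both to 0
    gives tissue parameters that are exact per group.

    ``anatomy_jitter`` scales per-subject anatomical variability (fractional
    SD of head size, striatal radius and GM thickness);
    ``alignment_jitter_mm`` adds a sub-voxel common-space misalignment.
    Anatomies and iron deviations are matched pairwise across groups:
    subject i of each group draws the same values before group effects are
    applied, so with all effect and variability knobs at zero a null cohort
    is exactly null.
    """

    n_per_group: int = 30
    atrophy_fraction: float = 0.15
    delta_r2star: float = 0.94
    iron_r1_slope: float = 0.035
    cortical_atrophy_fraction: float = 0.0
    noise_sigma: float = 0.005
    anatomy_jitter: float = 0.03
    alignment_jitter_mm: float = 0.4
    r2star_subject_sd: float = 1.0
    age_r2star_slope: float = 0.05
    covariates: dict[str, dict[str, CovariateDist]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATES.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0 <= self.atrophy_fraction < 1:
            raise ValueError("atrophy_fraction must lie in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.anatomy_jitter < 0:
            raise ValueError("anatomy_jitter must be >= 0")
        if self.alignment_jitter_mm < 0:
            raise ValueError("alignment_jitter_mm must be >= 0")
        if self.r2star_subject_sd < 0:
            raise ValueError("r2star_subject_sd must be >= 0")

    def reference_age(self) -> float:
        """Midpoint of the two groups' mean ages (age-coupling anchor)."""
        d = self.covariates["age"]
        return (d["patient"].mean + d["control"].mean) / 2.0


@dataclass
class SubjectRecord:
    """Group label plus covariates for one simulated subject."""

    id: str
    group: str  # "patient" | "control"
    age: float
    tiv: float
    bdi: float
    stai: float
    med_months: float


@dataclass
class SimulatedSubject:
    """One simulated subject: record, three contrasts and ground truth."""

    record: SubjectRecord
    volumes: dict[str, MultiEchoVolume]  # keys pdw, t1w, mtw
    phantom: Phantom


def _subject_phantom_spec(
    base: PhantomSpec,
    cohort: CohortSpec,
    group: str,
    anatomy_rng: np.random.Generator,
    age: float | None = None,
) -> PhantomSpec:
    """Per-subject phantom: shared anatomical jitter, then group effects."""
    jit = cohort.anatomy_jitter
    # Global head size: all lengths scale isotropically, so intracranial
    # volume varies ~3x the linear jitter across subjects, as in real
    # cohorts; without it TIV would be a near-proxy for the atrophy effect.
    brain_factor = 1.0 + np.clip(jit * anatomy_rng.standard_normal(), -3 * jit, 3 * jit)
    radius_factor = max(0.2, 1.0 + jit * anatomy_rng.standard_normal())
    thickness_factor = max(0.2, 1.0 + jit * anatomy_rng.standard_normal())
    # Sub-voxel misalignment: real co-registered brains never share a
    # common grid at sub-voxel precision, and exact alignment makes
    # interface partial-volume voxels degenerate (zero variance) across
    # subjects.  The offset is drawn with the other anatomy variables, so
    # matched subject pairs share it.
    offset = tuple(
        cohort.alignment_jitter_mm * anatomy_rng.uniform(-1.0, 1.0)
        for _ in range(3)
    )
    # Subject-level striatal iron: a pairwise-matched random deviation plus
    # an age trend; both feed R1 through the iron coupling.
    iron_dev = cohort.r2star_subject_sd * anatomy_rng.standard_normal()
    if age is not None and cohort.age_r2star_slope != 0:
        iron_dev += cohort.age_r2star_slope * (age - cohort.reference_age())
    striatum_radius = base.striatum_radius_mm * brain_factor * radius_factor
    gm_thickness = base.gm_thickness_mm * brain_factor * thickness_factor
    cortical_atrophy = base.cortical_atrophy_fraction
    tissues = dict(base.tissues)
    if group == "patient":
        striatum_radius *= 1.0 - cohort.atrophy_fraction
        cortical_atrophy = min(
            0.999, cortical_atrophy + cohort.cortical_atrophy_fraction
        )
        iron_dev += cohort.delta_r2star
    if iron_dev != 0:
        stri = tissues["striatal_gm"]
        tissues["striatal_gm"] = replace(
            stri,
            r2star=max(0.1, stri.r2star + iron_dev),
            r1=max(0.05, stri.r1 + cohort.iron_r1_slope * iron_dev),
        )
    return replace(
        base,
        brain_radius_mm=base.brain_radius_mm * brain_factor,
        csf_radius_mm=base.csf_radius_mm * brain_factor,
        striatum_offset_mm=base.striatum_offset_mm * brain_factor,
        striatum_radius_mm=striatum_radius,
        gm_thickness_mm=gm_thickness,
        cortical_atrophy_fraction=cortical_atrophy,
        center_offset_mm=offset,
        tissues=tissues,
    )


def _draw_covariates(
    cohort: CohortSpec, group: str, rng: np.random.Generator
) -> dict[str, float]:
    out = {}
    for name, dists in cohort.covariates.items():
        d = dists[group]
        value = d.mean + d.sd * rng.standard_normal() if d.sd > 0 else d.mean
        if name in ("med_months", "tiv"):
            value = max(0.0, value)
        out[name] = float(value)
    return out


def simulate_cohort(
    cohort: CohortSpec, phantom_spec: PhantomSpec | None = None
) -> Iterator[SimulatedSubject]:
    """Yield simulated subjects one at a time (controls first, then patients).

    Per-subject noise and covariate seeds derive deterministically from the
    cohort seed via :class:`numpy.random.SeedSequence`, so identical specs
    give bit-identical cohorts.  Subjects are yielded lazily because a full
    cohort of multi-echo volumes is large.
    """
    spec = phantom_spec if phantom_spec is not None else PhantomSpec()
    ss = np.random.SeedSequence(cohort.seed)
    noise_seeds = ss.spawn(2 * cohort.n_per_group)
    cov_rng = np.random.default_rng(ss.spawn(1)[0])
    anatomy_root = np.random.SeedSequence(entropy=cohort.seed, spawn_key=(999,))
    anatomy_seeds = anatomy_root.spawn(cohort.n_per_group)

    idx = 0
    for group in ("control", "patient"):
        for i in range(cohort.n_per_group):
            covs = _draw_covariates(cohort, group, cov_rng)
            anatomy_rng = np.random.default_rng(anatomy_seeds[i])
            sspec = _subject_phantom_spec(
                spec, cohort, group, anatomy_rng, age=covs["age"]
            )
            phantom = make_phantom(sspec)
            subject_rng = np.random.default_rng(noise_seeds[idx])
            volumes = {
                name: simulate_acquisition(
                    phantom.fields,
                    proto,
                    noise_sigma=cohort.noise_sigma,
                    seed=subject_rng,
                    wm_mask=phantom.wm_mask,
                    voxel_size_mm=sspec.voxel_size_mm,
                )
                for name, proto in DEFAULT_PROTOCOLS.items()
            }
            record = SubjectRecord(
                id=f"{group[:3]}{i + 1:03d}", group=group, **covs
            )
            yield SimulatedSubject(record=record, volumes=volumes, phantom=phantom)
            idx += 1
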