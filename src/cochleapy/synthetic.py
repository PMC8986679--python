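"""Synthetic cochlea and electrode phantoms with modality-specific noise.

The generator stands in for the imaged temporal bone: each ear is a
logarithmic-spiral lateral wall parameterized by the cochlear diameter A
and width B, with an optional 12-contact electrode array placed at fixed
arc-length pitch along an inward-offset insertion trajectory.  Observation
applies modality-specific landmark noise, a systematic lateral-wall bias
(medial in low-resolution scans of non-implanted ears, lateral under metal
artifact), and a recorded random rigid transform so that downstream
geometry cannot rely on the generation frame.

Coordinate convention at generation time: right-handed, millimetres,
modiolus on the z-axis at the origin, basal turn in the x-y plane, round
window at polar angle zero on the +x axis.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from . import geometry
from .exceptions import InsertionError, ParameterError
from .landmarks import LandmarkSet

MODALITY_NAMES = ("MSCT", "fpVCT", "fpVCT_SECO")

#: Nominal contact pitch of the FLEX28 array (12 contacts, 2.1 mm apart).
FLEX28_PITCH_MM = 2.1
N_CONTACTS = 12


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpiralParams:
    """Generative parameters of one cochlear lateral-wall spiral.

    ``basal_diameter_A`` and ``width_B`` are the diameters the A/B
    measurement should recover (mm); ``turns`` is the total angular extent
    in full turns; ``axial_height`` the apex drop along the modiolar axis
    (mm); ``wall_sampling_step`` the angular sampling of the wall polyline
    (radians).
    """

    basal_diameter_A: float = 9.0
    width_B: float = 6.5
    turns: float = 2.6
    axial_height: float = 2.5
    wall_sampling_step: float = 0.05

    def __post_init__(self) -> None:
        if not (self.basal_diameter_A >= self.width_B > 0):
            raise ParameterError(
                f"require A >= B > 0, got A={self.basal_diameter_A}, "
                f"B={self.width_B}"
            )
        if not (1.5 <= self.turns <= 3.5):
            raise ParameterError(f"turns must lie in [1.5, 3.5], got {self.turns}")
        if self.axial_height < 0:
            raise ParameterError("axial_height must be >= 0")
        if self.wall_sampling_step <= 0:
            raise ParameterError("wall_sampling_step must be > 0")


@dataclass(frozen=True)
class ElectrodeTruth:
    """Ground-truth electrode array: 12 contact centers (basal to apical)
    at fixed arc-length pitch along the insertion trajectory."""

    contact_centers: np.ndarray
    nominal_pitch: float
    insertion_offset: float
    insertion_start_depth: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "contact_centers",
            np.asarray(self.contact_centers, dtype=float).reshape(-1, 3),
        )
        if len(self.contact_centers) != N_CONTACTS:
            raise ParameterError(
                f"electrode array must have exactly {N_CONTACTS} contacts, "
                f"got {len(self.contact_centers)}"
            )


@dataclass(frozen=True)
class CochleaTruth:
    """Ground truth for one ear: wall curve, key landmarks, true A/B/CDL."""

    wall_points: np.ndarray
    modiolus: np.ndarray
    round_window: np.ndarray
    true_A: float
    true_B: float
    true_cdl_oc: float
    params: SpiralParams
    array: ElectrodeTruth | None = None

    @property
    def implanted(self) -> bool:
        return self.array is not None

    def with_array(self, array: ElectrodeTruth) -> "CochleaTruth":
        return replace(self, array=array)


@dataclass(frozen=True)
class ModalityProfile:
    """Observation model of one imaging modality.

    ``landmark_noise_sd`` is the isotropic localization noise for
    anatomical landmarks, ``contact_noise_sd`` for contact centers (mm).
    ``wall_bias`` displaces lateral-wall landmarks radially (negative =
    medial, toward the modiolus; positive = lateral); when an array is
    present ``implanted_extra_wall_bias`` is added on top, emulating metal
    artifact pushing the perceived wall outward.
    """

    name: str
    slice_thickness_um: float
    landmark_noise_sd: float
    wall_bias: float = 0.0
    contact_noise_sd: float = 0.0
    implanted_extra_wall_bias: float = 0.0

    def __post_init__(self) -> None:
        if self.landmark_noise_sd < 0 or self.contact_noise_sd < 0:
            raise ParameterError("noise SDs must be >= 0")
        if self.slice_thickness_um <= 0:
            raise ParameterError("slice_thickness_um must be > 0")


def default_profiles() -> dict[str, ModalityProfile]:
    """Default observation models for the three CT modalities.

    Landmark noise scales with slice thickness (0.25 x thickness in mm);
    the medial wall bias applies to the lower-resolution scans, and metal
    artifact adds a lateral bias in implanted MSCT and, weakly, fpVCT.
    """
    return {
        "MSCT": ModalityProfile(
            name="MSCT",
            slice_thickness_um=600.0,
            landmark_noise_sd=0.150,
            wall_bias=-0.2,
            contact_noise_sd=0.150,
            implanted_extra_wall_bias=0.4,
        ),
        "fpVCT": ModalityProfile(
            name="fpVCT",
            slice_thickness_um=466.0,
            landmark_noise_sd=0.117,
            wall_bias=-0.2,
            contact_noise_sd=0.117,
            implanted_extra_wall_bias=0.1,
        ),
        "fpVCT_SECO": ModalityProfile(
            name="fpVCT_SECO",
            slice_thickness_um=99.0,
            landmark_noise_sd=0.025,
            wall_bias=0.0,
            contact_noise_sd=0.025,
            implanted_extra_wall_bias=0.0,
        ),
    }


@dataclass(frozen=True)
class SubjectDistribution:
    """Population distribution of cochlear anatomy.

    A is drawn from a truncated normal; B follows A linearly with
    independent scatter; turns is normal, truncated to the valid range.
    Defaults land the simulated CDL_OC in the mid-30s mm typical of adult
    cochleae.
    """

    a_mean: float = 9.0
    a_sd: float = 0.4
    a_low: float = 8.0
    a_high: float = 10.5
    b_slope: float = 0.72
    b_sd: float = 0.15
    turns_mean: float = 2.6
    turns_sd: float = 0.15
    axial_height: float = 2.5
    wall_sampling_step: float = 0.05

    def draw(self, rng: np.random.Generator) -> SpiralParams:
        a = float(rng.normal(self.a_mean, self.a_sd))
        while not (self.a_low <= a <= self.a_high):
            a = float(rng.normal(self.a_mean, self.a_sd))
        b = float(self.b_slope * a + rng.normal(0.0, self.b_sd))
        b = min(max(b, 0.5 * a), 0.95 * a)  # keep A >= B > 0 physiologic
        t = float(np.clip(rng.normal(self.turns_mean, self.turns_sd), 1.5, 3.5))
        return SpiralParams(
            basal_diameter_A=a,
            width_B=b,
            turns=t,
            axial_height=self.axial_height,
            wall_sampling_step=self.wall_sampling_step,
        )


@dataclass(frozen=True)
class StudyDesign:
    """Sizes and structure of a simulated test-retest study.

    ``n_subjects`` is either a single count applied to every requested
    group or a mapping ``{group: count}``.  Each subject is observed by
    every modality in ``series_per_modality`` independent test series.
    """

    n_subjects: int | dict[int, int] = field(
        default_factory=lambda: {1: 20, 2: 20, 3: 10}
    )
    groups: tuple[int, ...] = (1, 2, 3)
    series_per_modality: int = 2
    subjects: SubjectDistribution = field(default_factory=SubjectDistribution)
    rng_seed: int = 0

    def group_sizes(self) -> dict[int, int]:
        sizes = {}
        for g in self.groups:
            if g not in (1, 2, 3):
                raise ParameterError(f"unknown group id {g}; groups are 1, 2, 3")
            n = self.n_subjects[g] if isinstance(self.n_subjects, dict) else self.n_subjects
            if n < 2:
                raise ParameterError("need at least 2 subjects per group")
            sizes[g] = int(n)
        return sizes

    def __post_init__(self) -> None:
        if self.series_per_modality < 2:
            raise ParameterError("series_per_modality must be >= 2")
        self.group_sizes()


# ---------------------------------------------------------------------------
# Geometry generation
# ---------------------------------------------------------------------------

#: Ratio of the lateral-wall spiral length to the hook-free organ-of-Corti
#: duct length; the wall spiral runs lateral to (and hence longer than)
#: the organ of Corti.
WALL_TO_OC_LENGTH_RATIO = 1.1


def _diameter_coefficients(A: float, B: float, k: float) -> tuple[float, float]:
    """Solve the two opposing-diameter constraints for the shifted
    logarithmic spiral ``r(theta) = c0 + c1*exp(-k*theta)``:

    ``r(0) + r(pi) = A`` and ``r(pi/2) + r(3pi/2) = B``

    which is linear in (c0, c1) for fixed decay rate ``k``.
    """
    if np.isclose(A, B):
        return A / 2.0, 0.0  # circle limit: zero decay amplitude
    e = np.exp(-k * np.array([np.pi, np.pi / 2.0, 3.0 * np.pi / 2.0]))
    m = np.array([[2.0, 1.0 + e[0]], [2.0, e[1] + e[2]]])
    c0, c1 = np.linalg.solve(m, np.array([A, B]))
    return float(c0), float(c1)


def _wall_arc_length(A: float, B: float, k: float, theta_max: float) -> float:
    """Planar arc length of the shifted spiral over [0, theta_max];
    returns 0 where the radius law goes non-positive (invalid decay)."""
    c0, c1 = _diameter_coefficients(A, B, k)
    theta = np.linspace(0.0, theta_max, 2048)
    r = c0 + c1 * np.exp(-k * theta)
    if np.any(r <= 0):
        return 0.0
    dr = -k * c1 * np.exp(-k * theta)
    return float(np.trapezoid(np.hypot(r, dr), theta))


def _solve_decay_rate(A: float, B: float, theta_max: float) -> float:
    """Choose the decay rate ``k`` so the wall arc length matches a
    realistic lateral-wall duct length.

    For any ``k`` the diameter constraints hold exactly; ``k`` only sets
    how fast the radius falls toward its apical plateau and hence the
    total spiral length.  The target is ``WALL_TO_OC_LENGTH_RATIO`` times
    the hook-free duct-length estimate from A and B.  Outside the
    bracketable range the nearest bracket endpoint is used.
    """
    from scipy.optimize import brentq

    from .geometry import cdl_oc

    target = WALL_TO_OC_LENGTH_RATIO * cdl_oc(A, B, include_hook=False, mode="grouped")
    k_lo, k_hi = 0.05, 5.0
    f = lambda k: _wall_arc_length(A, B, k, theta_max) - target  # noqa: E731
    if f(k_hi) <= 0:
        return k_hi
    if f(k_lo) >= 0:
        return k_lo
    return float(brentq(f, k_lo, k_hi, xtol=1e-10))


def generate_cochlea(
    params: SpiralParams,
    seed: int = 0,
    equation_mode: str = "as_printed",
) -> CochleaTruth:
    """Generate the ground-truth lateral-wall curve for one ear.

    The wall is a shifted logarithmic spiral ``r = c0 + c1*exp(-k*theta)``
    about the modiolus (monotone radius decay toward an apical plateau)
    whose opposing diameter sums reproduce A and B exactly; the decay rate
    is solved numerically so the spiral's arc length matches a realistic
    lateral-wall duct length (see :func:`_solve_decay_rate`).  z drops
    linearly with angle by ``axial_height`` over the full extent.  The
    round window is the first wall point.  ``true_cdl_oc`` is the elliptic
    circular approximation (with hook region) applied to the generative A
    and B.

    ``seed`` is accepted for interface uniformity; the wall construction
    is deterministic.
    """
    del seed  # deterministic construction
    A, B = params.basal_diameter_A, params.width_B
    theta_max = 2.0 * np.pi * params.turns
    k = _solve_decay_rate(A, B, theta_max)
    c0, c1 = _diameter_coefficients(A, B, k)
    n = int(np.ceil(theta_max / params.wall_sampling_step)) + 1
    theta = np.linspace(0.0, theta_max, n)
    r = c0 + c1 * np.exp(-k * theta)
    if np.any(r <= 0):
        raise ParameterError(
            f"no valid spiral for A={A}, B={B}: radius law goes non-positive"
        )
    z = -params.axial_height * theta / theta_max if theta_max > 0 else np.zeros_like(theta)
    wall = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return CochleaTruth(
        wall_points=wall,
        modiolus=np.zeros(3),
        round_window=wall[0].copy(),
        true_A=A,
        true_B=B,
        true_cdl_oc=geometry.cdl_oc(A, B, include_hook=True, mode=equation_mode),
        params=params,
    )


def place_contacts_along_polyline(
    polyline: np.ndarray,
    pitch: float,
    start_depth: float,
    n_contacts: int = N_CONTACTS,
) -> np.ndarray:
    """Place contact centers at arc lengths ``start_depth + j*pitch``
    (j = 0..n_contacts-1) along a polyline, by linear interpolation.

    Raises
    ------
    InsertionError
        If the polyline is shorter than the deepest requested contact;
        the error names the maximum feasible depth.
    """
    if pitch < 0:
        raise ParameterError("pitch must be >= 0")
    polyline = np.asarray(polyline, dtype=float)
    steps = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(steps)])
    deepest = start_depth + (n_contacts - 1) * pitch
    if deepest > s[-1] + 1e-12:
        raise InsertionError(requested_depth=deepest, max_feasible_depth=float(s[-1]))
    targets = start_depth + pitch * np.arange(n_contacts)
    out = np.empty((n_contacts, 3))
    for axis in range(3):
        out[:, axis] = np.interp(targets, s, polyline[:, axis])
    return out


def insertion_trajectory(truth: CochleaTruth, offset: float) -> np.ndarray:
    """Insertion trajectory: the wall curve shifted radially inward
    (toward the modiolar axis) by ``offset`` mm.

    The spiral radius eventually shrinks below the offset near the apex;
    the trajectory is truncated at the first wall point where that
    happens (an array never reaches the apex anyway).
    """
    wall = truth.wall_points
    rho = np.hypot(wall[:, 0], wall[:, 1])
    if rho[0] <= offset:
        raise ParameterError(
            f"inward offset {offset} mm exceeds the basal wall radius "
            f"{rho[0]:.3f} mm"
        )
    inside = np.flatnonzero(rho <= offset)
    end = int(inside[0]) if len(inside) else len(wall)
    wall = wall[:end]
    rho = rho[:end]
    scale = (rho - offset) / rho
    traj = wall.copy()
    traj[:, 0] *= scale
    traj[:, 1] *= scale
    return traj


def place_electrode(
    truth: CochleaTruth,
    pitch: float = FLEX28_PITCH_MM,
    offset: float = 0.25,
    start_depth: float = 1.0,
) -> ElectrodeTruth:
    """Place a 12-contact array along the insertion trajectory.

    The trajectory is the lateral wall offset inward by ``offset`` mm,
    arc-length parameterized from the round window; contact ``j`` sits at
    arc length ``start_depth + j*pitch``.
    """
    traj = insertion_trajectory(truth, offset)
    contacts = place_contacts_along_polyline(traj, pitch, start_depth)
    return ElectrodeTruth(
        contact_centers=contacts,
        nominal_pitch=pitch,
        insertion_offset=offset,
        insertion_start_depth=start_depth,
    )


# ---------------------------------------------------------------------------
# Observation model
# ---------------------------------------------------------------------------

def _observation_rng(seed: int, series_id: int, modality: str) -> np.random.Generator:
    # Distinct (seed, series, modality) triples give independent streams;
    # identical triples reproduce bit-identical draws.
    return np.random.default_rng(
        [int(seed), int(series_id), zlib.crc32(modality.encode("utf-8"))]
    )


def _radial_displace(points: np.ndarray, amount: float) -> np.ndarray:
    """Displace points radially in the x-y plane: positive = outward
    (lateral), negative = toward the modiolar axis (medial)."""
    if amount == 0.0:
        return points.copy()
    rho = np.hypot(points[:, 0], points[:, 1])
    out = points.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(rho > 0, (rho + amount) / rho, 1.0)
    out[:, 0] *= scale
    out[:, 1] *= scale
    return out


def _random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random rotation (QR of a Gaussian matrix) + translation."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(0.0, 10.0, size=3)
    return q, t


def observe(
    truth: CochleaTruth,
    profile: ModalityProfile,
    series_id: int,
    seed: int,
    subject_id: str = "S0",
    group: int = 1,
    apply_rigid_transform: bool = True,
) -> LandmarkSet:
    """Produce one noisy landmark observation of a ground-truth ear.

    Each landmark is the true position, plus the radial wall bias for wall
    landmarks (including the round window, which lies on the wall;
    ``implanted_extra_wall_bias`` is added when an array is present), plus
    isotropic Gaussian noise.  Contact centers receive ``contact_noise_sd``
    noise and no wall bias.  When ``apply_rigid_transform`` is set, a random
    rigid map (drawn from the same stream and recorded on the result) is
    applied to every point, so the observation frame carries no trace of
    the generation frame.
    """
    rng = _observation_rng(seed, series_id, profile.name)
    bias = profile.wall_bias + (
        profile.implanted_extra_wall_bias if truth.implanted else 0.0
    )
    wall = _radial_displace(truth.wall_points, bias)
    rw = _radial_displace(truth.round_window[None, :], bias)[0]
    mod = truth.modiolus.copy()

    sd = profile.landmark_noise_sd
    rw = rw + rng.normal(0.0, sd, size=3) if sd > 0 else rw
    mod = mod + rng.normal(0.0, sd, size=3) if sd > 0 else mod
    wall = wall + rng.normal(0.0, sd, size=wall.shape) if sd > 0 else wall

    contacts = None
    if truth.implanted:
        contacts = truth.array.contact_centers.copy()
        if profile.contact_noise_sd > 0:
            contacts = contacts + rng.normal(
                0.0, profile.contact_noise_sd, size=contacts.shape
            )

    transform = None
    if apply_rigid_transform:
        rot, trans = _random_rigid(rng)
        rw = rot @ rw + trans
        mod = rot @ mod + trans
        wall = wall @ rot.T + trans
        if contacts is not None:
            contacts = contacts @ rot.T + trans
        transform = (rot, trans)

    return LandmarkSet(
        subject_id=subject_id,
        group=group,
        modality=profile.name,
        series=series_id,
        round_window=rw,
        modiolus=mod,
        wall=wall,
        contacts=contacts,
        rigid_transform=transform,
    )


# ---------------------------------------------------------------------------
# Study simulation
# ---------------------------------------------------------------------------

def _group_implanted(group: int, modality: str) -> bool:
    """Which (group, modality) cells image an implanted ear.

    Group 1: non-implanted throughout.  Group 2: pre-operative MSCT of the
    non-implanted ear, post-operative fpVCT / fpVCT_SECO of the implanted
    ear (same subjects).  Group 3: implanted throughout.
    """
    if group == 1:
        return False
    if group == 2:
        return modality != "MSCT"
    if group == 3:
        return True
    raise ParameterError(f"unknown group id {group}; groups are 1, 2, 3")


def simulate_study(
    design: StudyDesign,
    profiles: dict[str, ModalityProfile] | list[ModalityProfile] | None = None,
    apply_rigid_transform: bool = True,
) -> list[LandmarkSet]:
    """Simulate the full study: per group, draw subject anatomies, place
    arrays where the group/modality cell is post-operative, and emit
    ``series_per_modality`` independent observations per subject and
    modality.  Fully deterministic given ``design.rng_seed``.
    """
    if profiles is None:
        profiles = default_profiles()
    if isinstance(profiles, list):
        profiles = {p.name: p for p in profiles}

    master = np.random.default_rng(design.rng_seed)
    out: list[LandmarkSet] = []
    for group, n in sorted(design.group_sizes().items()):
        for i in range(n):
            subject_id = f"G{group}S{i:03d}"
            params = design.subjects.draw(master)
            subject_seed = int(master.integers(0, 2**31 - 1))
            truth_plain = generate_cochlea(params)
            truth_impl = truth_plain.with_array(place_electrode(truth_plain))
            for profile in profiles.values():
                truth = (
                    truth_impl
                    if _group_implanted(group, profile.name)
                    else truth_plain
                )
                for series in range(1, design.series_per_modality + 1):
                    out.append(
                        observe(
                            truth,
                            profile,
                            series_id=series,
                            seed=subject_seed,
                            subject_id=subject_id,
                            group=group,
                            apply_rigid_transform=apply_rigid_transform,
                        )
                    )
    return out
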