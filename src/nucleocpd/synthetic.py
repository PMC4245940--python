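"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators cover the three experimental inputs:

* first-order deamination gel time courses (band intensities with
  multiplicative log-normal noise and a nonzero initial deaminated
  fraction, as phenol extraction produces in the real assay);
* periodic hydroxyl-radical cleavage profiles, either as a pure cosine
  or with the narrow protection troughs real footprints show;
* an idealized DNA ring on the nucleosome disc, with pyrimidine ring
  placeholders whose outward orientation varies with helical phase and
  placeholder B-factors equal to the radial distance, so structural
  operations have a construction with known ground truth.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .footprint import CleavageProfile
from .kinetics import BandMeasurement, TimeCourse
from .structure import Atom, NucleosomeStructure

__all__ = [
    "TimeCourseSpec",
    "ProfileSpec",
    "HelixSpec",
    "generate_time_course",
    "generate_profile",
    "generate_trough_profile",
    "generate_helix_coordinates",
    "structure_to_pdb",
]

#: Default sampling times (hours) spanning the half-life range of the
#: dyad-site series (3.5-41 h); geometric spacing resolves both the fast
#: and the slow regimes.
DEFAULT_TIMES_H = (0.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0)


@dataclass(frozen=True)
class TimeCourseSpec:
    """Ground truth for one simulated deamination time course.

    ``noise_sigma`` is the standard deviation of the log-normal
    multiplicative noise applied independently to each band intensity
    (phosphorimager counts are positive with roughly constant CV).
    ``initial_deaminated_fraction`` models deamination that occurs during
    sample work-up before the 37 degC incubation starts.
    """

    k_true: float
    yield_true: float = 0.12
    initial_deaminated_fraction: float = 0.05
    times_h: tuple[float, ...] = DEFAULT_TIMES_H
    noise_sigma: float = 0.05
    total_signal: float = 1000.0
    seed: int = 0
    site_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.k_true <= 0:
            raise ValueError("k_true must be positive")
        if not 0 < self.yield_true <= 1:
            raise ValueError("yield_true must be in (0, 1]")
        if not 0 <= self.initial_deaminated_fraction < 1:
            raise ValueError("initial_deaminated_fraction must be in [0, 1)")
        if self.noise_sigma < 0 or self.total_signal <= 0:
            raise ValueError("noise_sigma must be >= 0 and total_signal > 0")


def generate_time_course(spec: TimeCourseSpec) -> TimeCourse:
    """Simulate one site's band-intensity time course plus terminal aliquot.

    The true deaminated fraction follows
    ``f(t) = yield * (1 - (1 - f0) * exp(-k t))`` — first-order decay of
    the undeaminated CPD subpopulation, scaled by the photoproduct yield
    — and each band intensity gets an independent log-normal factor.
    The terminal (complete-deamination) aliquot is generated at
    ``f = yield`` with the same band noise.
    """
    rng = np.random.default_rng(spec.seed)
    f0 = spec.initial_deaminated_fraction
    measurements = []
    for t in spec.times_h:
        f = spec.yield_true * (1.0 - (1.0 - f0) * math.exp(-spec.k_true * t))
        eps_T = rng.lognormal(0.0, spec.noise_sigma) if spec.noise_sigma else 1.0
        eps_C = rng.lognormal(0.0, spec.noise_sigma) if spec.noise_sigma else 1.0
        measurements.append(
            BandMeasurement(
                time_h=t,
                intensity_mC=spec.total_signal * (1.0 - f) * eps_C,
                intensity_T=spec.total_signal * f * eps_T,
            )
        )
    eps_T = rng.lognormal(0.0, spec.noise_sigma) if spec.noise_sigma else 1.0
    eps_C = rng.lognormal(0.0, spec.noise_sigma) if spec.noise_sigma else 1.0
    terminal = BandMeasurement(
        time_h=spec.times_h[-1],
        intensity_mC=spec.total_signal * (1.0 - spec.yield_true) * eps_C,
        intensity_T=spec.total_signal * spec.yield_true * eps_T,
    )
    return TimeCourse(site_id=spec.site_id, measurements=tuple(measurements), terminal=terminal)


@dataclass(frozen=True)
class ProfileSpec:
    """Ground truth for a simulated cleavage profile."""

    period_bp: float = 10.4
    phase_bp: float = 76.0  # position of a cleavage maximum
    amplitude: float = 40.0
    baseline: float = 100.0
    noise_sigma: float = 0.0
    start: int = 55
    length: int = 42
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_bp <= 0 or self.length < 2:
            raise ValueError("period_bp must be positive and length >= 2")
        if not self.baseline > self.amplitude >= 0:
            raise ValueError("need baseline > amplitude >= 0 for nonnegative intensities")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.start, self.start + self.length, dtype=float)


def generate_profile(spec: ProfileSpec) -> CleavageProfile:
    """Cosine cleavage profile with additive Gaussian noise, clipped at 0."""
    rng = np.random.default_rng(spec.seed)
    x = spec.positions
    y = spec.baseline + spec.amplitude * np.cos(
        2.0 * np.pi * (x - spec.phase_bp) / spec.period_bp
    )
    if spec.noise_sigma:
        y = y + rng.normal(0.0, spec.noise_sigma, len(x))
    return CleavageProfile(positions=x, intensities=np.clip(y, 0.0, None))


def generate_trough_profile(spec: ProfileSpec, trough_sigma_bp: float = 1.4) -> CleavageProfile:
    """Periodic profile with narrow Gaussian protection troughs.

    Real nucleosome footprints are not sinusoidal: backbone protection is
    confined to the ~3 bp per turn that actually contact the histone
    core, while cleavage between contacts sits near its plateau.  This
    generator places a Gaussian dip of width ``trough_sigma_bp`` at every
    minimum position of the cosine model (``phase_bp + period/2`` mod
    ``period``), dropping from ``baseline + amplitude`` to
    ``baseline - amplitude`` at the trough centre.
    """
    rng = np.random.default_rng(spec.seed)
    x = spec.positions
    # distance from each position to the nearest trough centre
    offset = np.mod(x - (spec.phase_bp + spec.period_bp / 2.0), spec.period_bp)
    dist = np.minimum(offset, spec.period_bp - offset)
    dip = 2.0 * spec.amplitude * np.exp(-0.5 * (dist / trough_sigma_bp) ** 2)
    y = spec.baseline + spec.amplitude - dip
    if spec.noise_sigma:
        y = y + rng.normal(0.0, spec.noise_sigma, len(x))
    return CleavageProfile(positions=x, intensities=np.clip(y, 0.0, None))


@dataclass(frozen=True)
class HelixSpec:
    """Idealized DNA ring on the nucleosome disc.

    The duplex path is a flat circle of radius ``superhelix_radius_A``
    in the z = 0 plane (an idealization of the shallow superhelix; a
    positive ``superhelix_pitch_A`` lifts it into a true spiral, at the
    cost of a slight tilt of the phosphorus-cloud principal axes).
    ``bp_per_turn`` sets the helical twist that carries each base from
    outward-facing to inward-facing and back.
    """

    superhelix_radius_A: float = 41.9
    superhelix_pitch_A: float = 0.0
    bp_per_turn: float = 10.4
    n_bp: int = 147
    rise_per_bp_A: float = 3.4
    base_offset_A: float = 6.0  # ring centroid sits this far inside the backbone radius
    wobble_A: float = 2.0  # outward-facing bases sit this much further out
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.superhelix_radius_A, self.bp_per_turn, self.rise_per_bp_A) <= 0:
            raise ValueError("radius, bp_per_turn and rise must be positive")
        if self.superhelix_pitch_A < 0:
            raise ValueError("pitch must be >= 0")
        if self.n_bp < 12:
            raise ValueError("need at least 12 bp")


def generate_helix_coordinates(spec: HelixSpec) -> NucleosomeStructure:
    """Trace an idealized pyrimidine strand around the nucleosome disc.

    Residue ``i`` (1-based) sits at helical phase
    ``psi = 2*pi*(i-1)/bp_per_turn``: residue 1 faces exactly outward
    (its ring bisecting vector along the local radial), the residue
    half a turn later faces inward.  Ring centroids sit at radius
    ``R - base_offset + wobble*cos(psi)`` and every atom's placeholder
    B-factor is its radial distance from the z-axis, so by construction
    the orientation-angle minimum and the mean-B maximum coincide at the
    outward-facing residue.  Phosphorus atoms are placed on the backbone
    circle for axis estimation.
    """
    R = spec.superhelix_radius_A
    c = spec.superhelix_pitch_A / (2.0 * math.pi)
    # whole superhelical turns keep the phosphorus centroid exactly on the
    # rotation axis, so the estimated axis frame is exact by construction
    turns = max(1, round(spec.n_bp * spec.rise_per_bp_A / (2.0 * math.pi * math.hypot(R, c))))
    dphi = 2.0 * math.pi * turns / spec.n_bp
    atoms: list[Atom] = []
    # hexagon vertex phases chosen so the C6N1->N3C4 bisector lies along +b_hat
    vertex_deg = {name: -150.0 + 60.0 * k for k, name in enumerate(
        ("N1", "C2", "N3", "C4", "C5", "C6"))}
    ring_radius = 1.4
    for i in range(spec.n_bp):
        phi = i * dphi
        r_hat = np.array([math.cos(phi), math.sin(phi), 0.0])
        z_hat = np.array([0.0, 0.0, 1.0])
        t_hat = np.array([-math.sin(phi), math.cos(phi), 0.0])
        z_here = c * phi
        psi = 2.0 * math.pi * i / spec.bp_per_turn
        # backbone phosphorus on the superhelix path
        p_pos = R * r_hat + z_here * z_hat
        b_hat = math.cos(psi) * r_hat + math.sin(psi) * z_hat
        c_hat = np.cross(b_hat, t_hat)
        c_hat /= np.linalg.norm(c_hat)
        centroid = (R - spec.base_offset_A + spec.wobble_A * math.cos(psi)) * r_hat + z_here * z_hat

        def add(name: str, pos: np.ndarray) -> None:
            atoms.append(
                Atom(
                    name=name,
                    residue_name="DT",
                    residue_number=i + 1,
                    chain_id="I",
                    x=float(pos[0]),
                    y=float(pos[1]),
                    z=float(pos[2]),
                    b_factor=float(math.hypot(pos[0], pos[1])),
                    occupancy=1.0,
                )
            )

        add("P", p_pos)
        for name, deg in vertex_deg.items():
            theta = math.radians(deg)
            add(name, centroid + ring_radius * (math.cos(theta) * b_hat + math.sin(theta) * c_hat))
    return NucleosomeStructure.from_atoms(atoms)


def structure_to_pdb(structure: NucleosomeStructure) -> str:
    """Serialize a structure to PDB text (via gemmi)."""
    import gemmi

    st = gemmi.Structure()
    st.name = "synthetic"
    model = gemmi.Model("1")
    for chain_id, chain_df in structure.atoms.groupby("chain_id", sort=False):
        chain = gemmi.Chain(str(chain_id))
        for resno, res_df in chain_df.groupby("residue_number", sort=True):
            residue = gemmi.Residue()
            residue.name = res_df.residue_name.iloc[0]
            residue.seqid = gemmi.SeqId(int(resno), " ")
            for row in res_df.itertuples():
                atom = gemmi.Atom()
                atom.name = row.name
                atom.pos = gemmi.Position(row.x, row.y, row.z)
                atom.b_iso = row.b_factor
                atom.occ = row.occupancy
                atom.element = gemmi.Element(row.name[0])
                residue.add_atom(atom)
            chain.add_residue(residue)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()
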