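"""Ground-truth generators for every pipeline stage.

* sensorgram series mimicking a real multi-concentration biosensor run
  (model trace + linear drift + bulk refractive jump + Gaussian noise, with
  matching blank and reference-surface traces so that double referencing
  recovers the clean curve);
* toy two-chain complexes/trajectories with planted residue contacts that
  satisfy or violate the >=3-atoms-within-cutoff rule on a chosen occupancy
  schedule;
* trivial CD fixtures.

Every generator is deterministic given its integer seed (NumPy PCG64) and
emits a machine-readable ground-truth record so downstream checks never
hard-code expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contacts import Frame, Trajectory
from .errors import GenerationError, InvalidParameterError
from .kinetics import (
    InjectionSchedule,
    RateConstants,
    Sensorgram,
    simulate_two_compartment,
)

__all__ = [
    "SensorgramScenario",
    "SeriesBundle",
    "generate_sensorgram_series",
    "PlantedContact",
    "PlantedInterface",
    "generate_toy_complex",
    "SCENARIO_CATALOG",
    "DEFAULT_CONCENTRATIONS_M",
    "standard_schedule",
]

# standard experiment design: five analyte concentrations spanning
# 50-2000 nM, 360 s association, 600 s dissociation
DEFAULT_CONCENTRATIONS_M = (50e-9, 125e-9, 320e-9, 800e-9, 2000e-9)
DEFAULT_T_ASSOC_S = 360.0
DEFAULT_T_DISSOC_S = 600.0
DEFAULT_DT_S = 1.0
DEFAULT_LEAD_IN_S = 30.0


def standard_schedule(concentration: float, dt: float = DEFAULT_DT_S) -> InjectionSchedule:
    return InjectionSchedule(
        t_assoc=DEFAULT_T_ASSOC_S,
        t_dissoc=DEFAULT_T_DISSOC_S,
        concentration=concentration,
        dt=dt,
    )


@dataclass(frozen=True)
class SensorgramScenario:
    """Everything needed to generate one noisy concentration series."""

    truth: RateConstants
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS_M
    t_assoc: float = DEFAULT_T_ASSOC_S
    t_dissoc: float = DEFAULT_T_DISSOC_S
    dt: float = DEFAULT_DT_S
    lead_in: float = DEFAULT_LEAD_IN_S
    noise_sd: float = 0.5  # RU
    drift: float = 0.0  # RU/s, shared by sample and blank
    bulk_jump: float = 0.0  # RU, during injection, shared by sample and reference
    seed: int = 1234

    def __post_init__(self):
        if len(set(self.concentrations)) != len(self.concentrations):
            raise InvalidParameterError("concentrations must be distinct")
        if any(c < 0 for c in self.concentrations):
            raise InvalidParameterError("concentrations must be non-negative")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")


@dataclass
class SeriesBundle:
    """Generator output: raw curves plus the ground truth that made them."""

    samples: list[Sensorgram]
    blank: Sensorgram
    empty_surface: Sensorgram
    truth: dict


def _clean_trace(scenario: SensorgramScenario, concentration: float) -> Sensorgram:
    sched = InjectionSchedule(
        t_assoc=scenario.t_assoc,
        t_dissoc=scenario.t_dissoc,
        concentration=concentration,
        dt=scenario.dt,
    )
    return simulate_two_compartment(scenario.truth, sched, lead_in=scenario.lead_in)


def generate_sensorgram_series(scenario: SensorgramScenario) -> SeriesBundle:
    """Generate sample curves plus one blank and one reference-surface trace.

    sample(t)  = model(t) + drift*t + bulk_jump*1[injection] + noise
    blank(t)   =            drift*t                          + noise
    reference  =                      bulk_jump*1[injection] + noise

    so that (sample - blank) - reference recovers the model trace up to
    noise.  Deterministic given ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    samples = []
    time = None
    injection = None
    for conc in scenario.concentrations:
        clean = _clean_trace(scenario, conc)
        if time is None:
            time = clean.time
            injection = (time >= 0) & (time < scenario.t_assoc)
        artifacts = (
            scenario.drift * (time - time[0])
            + scenario.bulk_jump * injection
        )
        noisy = clean.response + artifacts + rng.normal(0.0, scenario.noise_sd, len(time))
        samples.append(
            Sensorgram(
                time=time.copy(),
                response=noisy,
                concentration=conc,
                phase_marks=clean.phase_marks,
                label=f"sample_{conc * 1e9:g}nM",
            )
        )
    marks = samples[0].phase_marks
    blank = Sensorgram(
        time=time.copy(),
        response=scenario.drift * (time - time[0])
        + rng.normal(0.0, scenario.noise_sd, len(time)),
        concentration=0.0,
        phase_marks=marks,
        label="blank",
    )
    empty = Sensorgram(
        time=time.copy(),
        response=scenario.bulk_jump * injection
        + rng.normal(0.0, scenario.noise_sd, len(time)),
        concentration=0.0,
        phase_marks=marks,
        label="empty_surface",
    )
    truth = {
        "k_on": scenario.truth.k_on,
        "k_off": scenario.truth.k_off,
        "r_max": scenario.truth.r_max,
        "k_t": scenario.truth.k_t,
        "k_d": scenario.truth.k_d,
        "concentrations_M": list(scenario.concentrations),
        "t_assoc_s": scenario.t_assoc,
        "t_dissoc_s": scenario.t_dissoc,
        "noise_sd_RU": scenario.noise_sd,
        "drift_RU_per_s": scenario.drift,
        "bulk_jump_RU": scenario.bulk_jump,
        "seed": scenario.seed,
    }
    return SeriesBundle(samples=samples, blank=blank, empty_surface=empty, truth=truth)


# ---------------------------------------------------------------------------
# bundled catalog of measured interaction constants (k_on 1/(M*s), k_off 1/s)
# spanning the 22.8 nM - 982 nM affinity range of the studied pairs

_CATALOG_RATES = {
    "FL1-MPP1": (4.50e4, 1.03e-3),
    "FL1-MPP1-Mut2": (1.68e3, 1.18e-3),
    "FL1-MPP1-Mut3": (3.75e3, 5.15e-4),
    "FL1-MPP1-Mut4": (8.13e3, 3.19e-4),
    "FL2-MPP1": (4.13e4, 1.28e-3),
    "FL2-MPP1-Mut2": (1.63e3, 1.60e-3),
    "FL2-MPP1-Mut3": (4.17e3, 8.28e-4),
    "FL2-MPP1-Mut4": (5.60e3, 2.81e-4),
}

SCENARIO_CATALOG: dict[str, SensorgramScenario] = {
    name: SensorgramScenario(
        truth=RateConstants(k_on=k_on, k_off=k_off, r_max=100.0, k_t=1e8),
        noise_sd=0.5,
    )
    for name, (k_on, k_off) in _CATALOG_RATES.items()
}


# ---------------------------------------------------------------------------
# toy complexes with planted interfaces


@dataclass(frozen=True)
class PlantedContact:
    """One residue pair to plant.

    ``n_atoms_close`` atoms of the chain-A residue are placed at
    ``target_distance`` from chain-B atoms whenever the contact is "on";
    remaining atoms stay beyond 5 Å.  ``occupancy`` sets the fraction of
    frames in which the contact is on.
    """

    residue_a: int
    residue_b: int
    n_atoms_close: int = 3
    target_distance: float = 2.5
    occupancy: float = 1.0

    def __post_init__(self):
        if self.target_distance <= 0:
            raise InvalidParameterError("target_distance must be positive")
        if not (0.0 <= self.occupancy <= 1.0):
            raise InvalidParameterError("occupancy must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedInterface:
    """A toy two-chain system with a known contact ground truth."""

    n_residues_a: int = 8
    n_residues_b: int = 8
    contacts: tuple[PlantedContact, ...] = ()
    jitter_sd: float = 0.0  # Å, Gaussian positional noise per frame
    charge_a: float = 0.0  # per-atom charge on planted chain-A residues
    charge_b: float = 0.0

    def __post_init__(self):
        for c in self.contacts:
            if not (1 <= c.residue_a <= self.n_residues_a):
                raise InvalidParameterError(f"residue_a {c.residue_a} out of range")
            if not (1 <= c.residue_b <= self.n_residues_b):
                raise InvalidParameterError(f"residue_b {c.residue_b} out of range")


ATOMS_PER_RESIDUE = 5  # alanine-like pseudo-residue
_RESIDUE_SPACING = 8.0  # Å along the chain axis
_CHAIN_SEPARATION = 30.0  # Å between the chains when not in contact
# atom spacing wide enough that a planted atom at ~2.5 Å from its matching
# partner atom is NOT within 3 Å of the partner's neighbours
# (sqrt(2.5^2 + 3.5^2) = 4.3 Å), keeping planted atom counts exact
_ATOM_SPACING = 3.5  # Å between atoms of one pseudo-residue


def _chain_positions(n_res: int, y: float) -> np.ndarray:
    """Atoms of one chain: residues along x, atoms of a residue along z."""
    pos = np.empty((n_res * ATOMS_PER_RESIDUE, 3))
    for r in range(n_res):
        for a in range(ATOMS_PER_RESIDUE):
            pos[r * ATOMS_PER_RESIDUE + a] = (
                r * _RESIDUE_SPACING,
                y,
                a * _ATOM_SPACING,
            )
    return pos


def generate_toy_complex(
    interface: PlantedInterface, n_frames: int, seed: int = 1234
) -> tuple[Trajectory, list[dict]]:
    """Build a trajectory realizing the planted interface.

    Returns the trajectory and a truth table: one record per planted
    contact with the frame indices in which it is on.

    Raises
    ------
    GenerationError
        If the requested geometry would place atoms closer than 0.5 Å.
    """
    if n_frames < 1:
        raise InvalidParameterError("n_frames must be >= 1")
    for c in interface.contacts:
        if c.target_distance < 0.5:
            raise GenerationError(
                f"target distance {c.target_distance} Å < 0.5 Å would overlap atoms"
            )
    rng = np.random.default_rng(seed)

    na = interface.n_residues_a * ATOMS_PER_RESIDUE
    nb = interface.n_residues_b * ATOMS_PER_RESIDUE
    base_a = _chain_positions(interface.n_residues_a, 0.0)
    base_b = _chain_positions(interface.n_residues_b, _CHAIN_SEPARATION)

    res_numbers = np.concatenate(
        [
            np.repeat(np.arange(1, interface.n_residues_a + 1), ATOMS_PER_RESIDUE),
            np.repeat(np.arange(1, interface.n_residues_b + 1), ATOMS_PER_RESIDUE),
        ]
    )
    res_names = np.full(na + nb, "ALA", dtype="<U3")
    tags = np.array(["A"] * na + ["B"] * nb)
    charges = np.zeros(na + nb)

    # on/off schedule per contact: deterministic frame subset of the right size
    truth = []
    on_frames: list[np.ndarray] = []
    for c in interface.contacts:
        n_on = int(round(c.occupancy * n_frames))
        frames_on = np.sort(rng.permutation(n_frames)[:n_on])
        on_frames.append(frames_on)
        truth.append(
            {
                "residue_a": c.residue_a,
                "residue_b": c.residue_b,
                "n_atoms_close": c.n_atoms_close,
                "target_distance": c.target_distance,
                "frames_on": frames_on.tolist(),
                "occupancy": n_on / n_frames,
            }
        )
        if interface.charge_a or interface.charge_b:
            ia = (res_numbers[:na] == c.residue_a)
            charges[:na][ia] = interface.charge_a
            ib = (res_numbers[na:] == c.residue_b)
            charges[na:][ib] = interface.charge_b

    frames = []
    for f in range(n_frames):
        pos = np.vstack([base_a, base_b]).copy()
        for j, (c, frames_on) in enumerate(zip(interface.contacts, on_frames)):
            if f not in frames_on:
                continue
            # move n_atoms_close atoms of residue_a to target_distance from
            # the matching atoms of residue_b; the rest stay far away.  Each
            # contact approaches from its own direction in the x-y plane so
            # that several contacts can anchor on one partner residue
            # without overlapping atoms.
            theta = 0.7 * j
            direction = np.array([np.sin(theta), np.cos(theta), 0.0])
            a0 = (c.residue_a - 1) * ATOMS_PER_RESIDUE
            b0 = na + (c.residue_b - 1) * ATOMS_PER_RESIDUE
            for k in range(c.n_atoms_close):
                pos[a0 + k] = pos[b0 + k] + c.target_distance * direction
        if interface.jitter_sd > 0:
            pos += rng.normal(0.0, interface.jitter_sd, pos.shape)
        d_min_check = 0.5
        frame = Frame(
            positions=pos,
            residue_names=res_names.copy(),
            residue_numbers=res_numbers.copy(),
            molecule_tags=tags.copy(),
            charges=charges.copy(),
            frame_index=f,
        )
        # cheap overlap guard on the atoms we actually moved
        from scipy.spatial import cKDTree

        tree = cKDTree(pos)
        close = tree.query_pairs(d_min_check)
        if close:
            raise GenerationError(
                f"frame {f}: {len(close)} atom pairs closer than {d_min_check} Å"
            )
        frames.append(frame)
    return Trajectory(frames), truth
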