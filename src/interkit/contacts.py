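"""Residue-level cross-molecule contact mapping on coordinate frames.

A residue pair (a on molecule A, b on molecule B) is flagged as a contact in
a frame when at least ``min_atoms`` distinct atoms of one of the two
residues lie within ``cutoff`` of atoms of the partner residue.  The rule is
applied symmetrically from both molecules and the triggering side is
recorded.  Aggregating flags over the frames of a trajectory yields
per-pair occupancies; pairs adjacent in sequence whose frame sets largely
overlap are grouped into binding sites.  Sites are ranked by the magnitude
of a screened-free Coulomb interaction energy and classified as stable
unless that magnitude falls below a fraction of the strongest site's.

Coordinates are assumed whole and imaged (no periodic wrapping is applied).
Hydrogens, if present in the input, participate like any other atom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidParameterError

__all__ = [
    "Frame",
    "Trajectory",
    "FlaggedPair",
    "ContactSite",
    "flag_contacts",
    "aggregate_sites",
    "electrostatic_score",
    "score_sites",
    "classify_stability",
]

COULOMB_CONSTANT = 332.0636  # kcal*Å/(mol*e²)
ELECTROSTATIC_CUTOFF = 12.0  # Å

ResidueKey = tuple[str, int]  # (3-letter name, residue number)


@dataclass
class Frame:
    """One coordinate frame of a two-molecule system.

    Parallel per-atom arrays; ``molecule_tags`` holds 'A' or 'B'.  Partial
    charges default to zero when unknown.
    """

    positions: np.ndarray
    residue_names: np.ndarray
    residue_numbers: np.ndarray
    molecule_tags: np.ndarray
    charges: np.ndarray | None = None
    atom_ids: np.ndarray | None = None
    frame_index: int = 0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise InvalidParameterError("positions must be (N, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise InvalidParameterError("positions must be finite")
        n = len(self.positions)
        self.residue_names = np.asarray(self.residue_names)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.molecule_tags = np.asarray(self.molecule_tags)
        tags = set(np.unique(self.molecule_tags))
        if not tags <= {"A", "B"}:
            raise InvalidParameterError(f"molecule tags must be A/B, got {tags}")
        if self.charges is None:
            self.charges = np.zeros(n)
        else:
            self.charges = np.asarray(self.charges, dtype=float)
        if self.atom_ids is None:
            self.atom_ids = np.arange(n)
        for arr in (self.residue_names, self.residue_numbers, self.molecule_tags,
                    self.charges, self.atom_ids):
            if len(arr) != n:
                raise InvalidParameterError("per-atom arrays must share length")

    def __len__(self) -> int:
        return len(self.positions)

    def mask(self, tag: str) -> np.ndarray:
        return self.molecule_tags == tag

    def residues(self, tag: str) -> list[ResidueKey]:
        m = self.mask(tag)
        seen: dict[int, str] = {}
        for name, num in zip(self.residue_names[m], self.residue_numbers[m]):
            seen.setdefault(int(num), str(name))
        return [(seen[num], num) for num in sorted(seen)]


class Trajectory:
    """An ordered list of frames with a constant atom roster."""

    def __init__(self, frames: list[Frame]):
        if not frames:
            raise InvalidParameterError("trajectory must contain at least one frame")
        ref = frames[0]
        for f in frames[1:]:
            same = (
                len(f) == len(ref)
                and np.array_equal(f.residue_numbers, ref.residue_numbers)
                and np.array_equal(f.molecule_tags, ref.molecule_tags)
                and np.array_equal(f.residue_names, ref.residue_names)
            )
            if not same:
                raise InvalidParameterError("atom roster differs between frames")
        self.frames = list(frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


@dataclass(frozen=True)
class FlaggedPair:
    residue_a: ResidueKey
    residue_b: ResidueKey
    n_atoms_a: int  # atoms of residue A within cutoff of residue B
    n_atoms_b: int
    triggered_by: str  # "A", "B" or "AB"


@dataclass
class ContactSite:
    """A cross-molecule residue pair aggregated over a trajectory."""

    residue_a: ResidueKey
    residue_b: ResidueKey
    frames_flagged: list[int]
    occupancy: float
    electrostatic_score: float = 0.0
    stable: bool | None = None
    group_id: int = -1

    def __post_init__(self):
        if not (0.0 <= self.occupancy <= 1.0):
            raise InvalidParameterError(f"occupancy {self.occupancy} outside [0, 1]")
        self.frames_flagged = sorted(set(self.frames_flagged))


def flag_contacts(
    frame: Frame, cutoff: float = 3.0, min_atoms: int = 3
) -> list[FlaggedPair]:
    """Flag residue pairs in contact in one frame.

    A pair is flagged when >= ``min_atoms`` distinct atoms of either residue
    lie within ``cutoff`` Å of atoms of the partner residue (an atom counts
    once no matter how many partner atoms it approaches).  Output is sorted
    by (residue number A, residue number B) and deterministic.

    Raises
    ------
    InvalidParameterError
        If the frame lacks one of the molecules or the cutoff is not positive.
    """
    if cutoff <= 0:
        raise InvalidParameterError(f"cutoff must be positive, got {cutoff}")
    if min_atoms < 1:
        raise InvalidParameterError(f"min_atoms must be >= 1, got {min_atoms}")
    mask_a = frame.mask("A")
    mask_b = frame.mask("B")
    if not mask_a.any() or not mask_b.any():
        raise InvalidParameterError("frame must contain both molecules A and B")

    idx_a = np.flatnonzero(mask_a)
    idx_b = np.flatnonzero(mask_b)
    tree_a = cKDTree(frame.positions[idx_a])
    tree_b = cKDTree(frame.positions[idx_b])
    pairs = tree_a.query_ball_tree(tree_b, r=cutoff)

    # per residue pair: the sets of distinct atoms within cutoff on each side
    atoms_a: dict[tuple[int, int], set[int]] = {}
    atoms_b: dict[tuple[int, int], set[int]] = {}
    for ia_local, neighbors in enumerate(pairs):
        if not neighbors:
            continue
        ia = idx_a[ia_local]
        ra = int(frame.residue_numbers[ia])
        for ib_local in neighbors:
            ib = idx_b[ib_local]
            rb = int(frame.residue_numbers[ib])
            key = (ra, rb)
            atoms_a.setdefault(key, set()).add(int(ia))
            atoms_b.setdefault(key, set()).add(int(ib))

    name_a = {int(n): str(s) for n, s in zip(frame.residue_numbers[mask_a],
                                             frame.residue_names[mask_a])}
    name_b = {int(n): str(s) for n, s in zip(frame.residue_numbers[mask_b],
                                             frame.residue_names[mask_b])}
    out = []
    for key in sorted(atoms_a):
        na = len(atoms_a[key])
        nb = len(atoms_b[key])
        trig = ("A" if na >= min_atoms else "") + ("B" if nb >= min_atoms else "")
        if not trig:
            continue
        ra, rb = key
        out.append(
            FlaggedPair(
                residue_a=(name_a[ra], ra),
                residue_b=(name_b[rb], rb),
                n_atoms_a=na,
                n_atoms_b=nb,
                triggered_by="AB" if trig == "AB" else trig,
            )
        )
    return out


def _group_sites(sites: list[ContactSite], jaccard_min: float = 0.5,
                 seq_gap: int = 2) -> None:
    """Assign group ids: sequence-adjacent pairs sharing frames form one site."""
    n = len(sites)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    frame_sets = [set(s.frames_flagged) for s in sites]
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = sites[i], sites[j]
            if abs(si.residue_a[1] - sj.residue_a[1]) > seq_gap:
                continue
            if abs(si.residue_b[1] - sj.residue_b[1]) > seq_gap:
                continue
            inter = len(frame_sets[i] & frame_sets[j])
            uni = len(frame_sets[i] | frame_sets[j])
            if uni and inter / uni >= jaccard_min:
                union(i, j)

    roots: dict[int, int] = {}
    for i, s in enumerate(sites):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots)
        s.group_id = roots[r]


def aggregate_sites(
    trajectory: Trajectory, cutoff: float = 3.0, min_atoms: int = 3
) -> list[ContactSite]:
    """Union per-frame contact flags into per-pair sites with occupancies.

    Occupancy is the fraction of frames in which the pair was flagged.
    Sites whose residues are within 2 positions on both molecules and whose
    frame sets overlap (Jaccard >= 0.5) share a ``group_id``.
    """
    flags: dict[tuple[ResidueKey, ResidueKey], list[int]] = {}
    for i, frame in enumerate(trajectory):
        for pair in flag_contacts(frame, cutoff=cutoff, min_atoms=min_atoms):
            flags.setdefault((pair.residue_a, pair.residue_b), []).append(i)
    n_frames = len(trajectory)
    sites = [
        ContactSite(
            residue_a=a,
            residue_b=b,
            frames_flagged=fr,
            occupancy=len(set(fr)) / n_frames,
        )
        for (a, b), fr in sorted(flags.items(), key=lambda kv: (kv[0][0][1], kv[0][1][1]))
    ]
    _group_sites(sites)
    return sites


def electrostatic_score(
    site: ContactSite,
    frame: Frame,
    dielectric: float = 1.0,
    distance_cutoff: float = ELECTROSTATIC_CUTOFF,
) -> float:
    """Coulomb interaction energy of a site's residue pair in one frame.

    Sums 332.0636 * q_i * q_j / (dielectric * r_ij) over cross-molecule atom
    pairs of the site's residues within ``distance_cutoff`` Å.  The sign is
    retained; ranking uses the magnitude.  Warns and returns 0.0 when all
    involved charges vanish.
    """
    if dielectric <= 0:
        raise InvalidParameterError(f"dielectric must be positive, got {dielectric}")
    sel_a = frame.mask("A") & (frame.residue_numbers == site.residue_a[1])
    sel_b = frame.mask("B") & (frame.residue_numbers == site.residue_b[1])
    qa = frame.charges[sel_a]
    qb = frame.charges[sel_b]
    if np.all(qa == 0) and np.all(qb == 0):
        warnings.warn(
            f"all partial charges of site {site.residue_a}/{site.residue_b} "
            "are zero: electrostatic score is 0",
            UserWarning,
            stacklevel=2,
        )
        return 0.0
    pa = frame.positions[sel_a]
    pb = frame.positions[sel_b]
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    with np.errstate(divide="ignore"):
        e = COULOMB_CONSTANT * qa[:, None] * qb[None, :] / (dielectric * d)
    e = np.where((d > 0) & (d <= distance_cutoff), e, 0.0)
    return float(e.sum())


def score_sites(
    sites: list[ContactSite],
    trajectory: Trajectory,
    dielectric: float = 1.0,
    distance_cutoff: float = ELECTROSTATIC_CUTOFF,
) -> list[ContactSite]:
    """Attach to each site its Coulomb energy averaged over flagged frames."""
    for site in sites:
        if not site.frames_flagged:
            site.electrostatic_score = 0.0
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            vals = [
                electrostatic_score(
                    site, trajectory[i], dielectric=dielectric,
                    distance_cutoff=distance_cutoff,
                )
                for i in site.frames_flagged
            ]
        site.electrostatic_score = float(np.mean(vals))
    return sites


def classify_stability(
    sites: list[ContactSite], threshold_fraction: float = 0.10
) -> list[ContactSite]:
    """Label sites stable/unstable by relative electrostatic strength.

    A site is stable iff |score| >= threshold_fraction * max |score| over the
    list; a singleton list is stable by construction (it is the maximum).

    Raises
    ------
    InvalidParameterError
        If the list is empty.
    """
    if not sites:
        raise InvalidParameterError("cannot classify an empty site list")
    max_mag = max(abs(s.electrostatic_score) for s in sites)
    for s in sites:
        s.stable = abs(s.electrostatic_score) >= threshold_fraction * max_mag
    return sites
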