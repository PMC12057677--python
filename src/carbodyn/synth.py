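"""Ground-truth-labeled synthetic inputs for every analysis stage.

Two levels of generator are provided.  Stochastic generators produce state
sequences from a continuous-time Markov model with prescribed stationary
populations (emulating the conformer dynamics of a nanosecond reactive
trajectory), episode scripts with prescribed hop-count/endpoint statistics,
and coordination-number samples Boltzmann-distributed on a reference
free-energy profile.  The atomistic renderer turns scripts or state
sequences into coordinate trajectories — an idealized planar acid plus
lattice waters, with scripted hops realized by relocating the mobile proton
between host oxygens — that the full geometric pipeline can analyze and
whose analysis must recover the generator parameters.  Waters beyond the
scripted hydrogen-bond partners are decorative lattice fill; no water-water
dynamics realism is attempted, because the pipeline under test is geometric
and graph-based, not dynamical.

Every generator is seed-deterministic and emits a ground-truth log.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from carbodyn.constants import kT as kT_at
from carbodyn.io import CellSpec, Trajectory
from carbodyn.observables import FreeEnergyProfile, dissociation_delta_f
from carbodyn.topology import StateSequence, dihedral

logger = logging.getLogger(__name__)

_FREE_CELL = CellSpec((1000.0, 1000.0, 1000.0), periodic=(False, False, False))


class PackingError(ValueError):
    """Requested water count does not fit the box at safe separations."""


# ---------------------------------------------------------------------------
# Markov state model
# ---------------------------------------------------------------------------

@dataclass
class MarkovModel:
    """Continuous-time Markov model sampled on a frame grid.

    ``rates`` is the transition-rate matrix Q (1/ps, off-diagonals >= 0,
    rows sum to zero); the per-step embedded transition matrix is
    P = I + Q dt, which requires dt small enough that all rows stay
    probabilities.
    """

    states: list[str]
    rates: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        n = len(self.states)
        if self.rates.shape != (n, n):
            raise ValueError("rate matrix shape must match state count")
        off = self.rates - np.diag(np.diag(self.rates))
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if not np.allclose(self.rates.sum(axis=1), 0, atol=1e-10):
            raise ValueError("rate-matrix rows must sum to zero")

    @property
    def transition_matrix(self) -> np.ndarray:
        P = np.eye(len(self.states)) + self.rates * self.dt
        if np.any(P < -1e-12):
            raise ValueError("dt too large: embedded transition matrix not stochastic")
        return np.clip(P, 0.0, None)

    def stationary(self) -> np.ndarray:
        """Stationary distribution (left null vector of Q)."""
        n = len(self.states)
        A = np.vstack([self.rates.T, np.ones(n)])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        return pi

    @classmethod
    def from_stationary(
        cls,
        states: Sequence[str],
        stationary: Sequence[float],
        flows: Sequence[tuple[str, str, float]],
        dt: float,
    ) -> "MarkovModel":
        """Detailed-balance rate matrix from target populations and
        symmetric exchange flows (probability/ps per state pair)."""
        states = list(states)
        pi = np.asarray(stationary, dtype=float)
        if not np.isclose(pi.sum(), 1.0, atol=1e-8):
            raise ValueError("stationary distribution must sum to 1")
        idx = {s: i for i, s in enumerate(states)}
        Q = np.zeros((len(states), len(states)))
        for a, b, flow in flows:
            i, j = idx[a], idx[b]
            Q[i, j] += flow / pi[i]
            Q[j, i] += flow / pi[j]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return cls(states=states, rates=Q, dt=dt)


def generate_state_sequence(model: MarkovModel, n_steps: int, seed: int) -> StateSequence:
    """Seed-deterministic label sequence from the embedded discrete chain.

    Simulated by geometric sojourn sampling, which is distributionally
    identical to per-step transitions and much faster for stiff chains.
    """
    rng = np.random.default_rng(seed)
    P = model.transition_matrix
    n_states = len(model.states)
    reachable = _reachable_states(P)
    if len(reachable) < n_states:
        logger.warning(
            "states unreachable from state 0: %s",
            [model.states[i] for i in range(n_states) if i not in reachable],
        )
    codes = np.empty(n_steps, dtype=np.int16)
    state = 0
    pos = 0
    while pos < n_steps:
        p_stay = P[state, state]
        p_leave = 1.0 - p_stay
        if p_leave < 1e-15:
            codes[pos:] = state
            break
        sojourn = int(rng.geometric(p_leave))
        sojourn = min(sojourn, n_steps - pos)
        codes[pos : pos + sojourn] = state
        pos += sojourn
        if pos >= n_steps:
            break
        jump = P[state].copy()
        jump[state] = 0.0
        jump /= jump.sum()
        state = int(rng.choice(n_states, p=jump))
    labels = [model.states[c] for c in codes]
    return StateSequence(
        labels=labels,
        dihedrals=np.full((n_steps, 2), np.nan),
        times=np.arange(n_steps) * model.dt,
    )


def _reachable_states(P: np.ndarray) -> set[int]:
    n = len(P)
    seen = {0}
    frontier = [0]
    while frontier:
        s = frontier.pop()
        for j in range(n):
            if j not in seen and P[s, j] > 0:
                seen.add(j)
                frontier.append(j)
    return seen


# ---------------------------------------------------------------------------
# episode scripts
# ---------------------------------------------------------------------------

@dataclass
class EpisodeScript:
    """Prescription for one dissociation episode.

    ``hosts`` is the chain of water indices (local ids into the rendered
    water list) visited between dissociation and recombination; the hop
    count is ``len(hosts) + 1`` (dissociation and recombination inclusive).
    ``rattles`` are (position, water) pairs: a one-frame excursion to
    ``water`` inserted inside the residence of chain host ``position``.
    """

    source: str  # CC / CT
    hosts: list[int]
    endpoint: str  # homing / exploratory
    rattles: list[tuple[int, int]] = field(default_factory=list)
    hold_frames: int = 3

    @property
    def n_hops(self) -> int:
        return len(self.hosts) + 1


def generate_episode_stream(
    config: dict,
    n_episodes: int,
    seed: int,
    n_waters: int | None = None,
) -> tuple[list[EpisodeScript], dict]:
    """Draw i.i.d. episode scripts and return them with ground truth.

    ``config`` keys: ``source_weights`` (conformer -> probability),
    ``hop_distribution`` (hop count -> probability, counts >= 2),
    ``endpoint_probs`` (conformer -> {homing: p}), ``rattle_rate``
    (expected rattles per episode).
    """
    rng = np.random.default_rng(seed)
    sources = sorted(config["source_weights"])
    w = np.array([config["source_weights"][s] for s in sources], dtype=float)
    if not np.isclose(w.sum(), 1.0, atol=1e-8):
        raise ValueError("source_weights must sum to 1")
    hop_counts = sorted(int(k) for k in config["hop_distribution"])
    hop_p = np.array([config["hop_distribution"][k] for k in hop_counts], dtype=float)
    if not np.isclose(hop_p.sum(), 1.0, atol=1e-8):
        raise ValueError("hop_distribution must sum to 1")
    if min(hop_counts) < 2:
        raise ValueError("hop counts must be >= 2")
    endpoint_probs = config["endpoint_probs"]
    for s in sources:
        if not 0 <= endpoint_probs[s]["homing"] <= 1:
            raise ValueError("endpoint probabilities must be in [0, 1]")
    rattle_rate = float(config.get("rattle_rate", 0.0))
    if n_waters is None:
        n_waters = int(config.get("n_waters", 12))
    scripts: list[EpisodeScript] = []
    for _ in range(n_episodes):
        source = sources[int(rng.choice(len(sources), p=w))]
        n_hops = hop_counts[int(rng.choice(len(hop_counts), p=hop_p))]
        if n_hops - 1 > n_waters:
            raise ValueError("not enough waters for the longest hop chain")
        # non-backtracking walk over water ids
        hosts = [int(rng.integers(n_waters))]
        while len(hosts) < n_hops - 1:
            nxt = int(rng.integers(n_waters))
            if nxt != hosts[-1]:
                hosts.append(nxt)
        homing = rng.random() < endpoint_probs[source]["homing"]
        rattles: list[tuple[int, int]] = []
        used: dict[int, set[int]] = {}
        for _ in range(rng.poisson(rattle_rate)):
            pos = int(rng.integers(len(hosts)))
            taken = used.setdefault(pos, {hosts[pos]})
            if len(taken) >= n_waters:
                continue
            other = int(rng.integers(n_waters))
            while other in taken:
                other = (other + 1) % n_waters
            taken.add(other)
            rattles.append((pos, other))
        scripts.append(
            EpisodeScript(
                source=source,
                hosts=hosts,
                endpoint="homing" if homing else "exploratory",
                rattles=rattles,
            )
        )
    truth = ground_truth_summary(scripts)
    truth["seed"] = seed
    return scripts, truth


def ground_truth_summary(scripts: Sequence[EpisodeScript]) -> dict:
    """Source fractions, homing fractions and hop histogram of a script list."""
    n = len(scripts)
    sources = sorted({s.source for s in scripts})
    hist: dict[str, dict[int, int]] = {s: {} for s in sources}
    for s in scripts:
        hist[s.source][s.n_hops] = hist[s.source].get(s.n_hops, 0) + 1
    return {
        "n_episodes": n,
        "source_fraction_pct": {
            s: 100.0 * sum(x.source == s for x in scripts) / n for s in sources
        },
        "homing_fraction_pct": {
            s: 100.0
            * sum(x.endpoint == "homing" for x in scripts if x.source == s)
            / max(1, sum(x.source == s for x in scripts))
            for s in sources
        },
        "hop_histogram": {s: dict(sorted(d.items())) for s, d in hist.items()},
    }


# ---------------------------------------------------------------------------
# geometry templates
# ---------------------------------------------------------------------------

#: standard small-molecule internal coordinates (Angstrom, degrees)
C_OH_BOND = 1.34
C_O_DOUBLE = 1.21
O_H_BOND = 0.97
WATER_OH = 0.96
WATER_ANGLE = 104.5
COH_ANGLE = 106.0

# solute atom order: C, O_carbonyl, O_hyd1, O_hyd2, H1, H2
SOLUTE_ATOMS = ["C", "O", "O", "O", "H", "H"]
IDX_C, IDX_OC, IDX_O1, IDX_O2, IDX_H1, IDX_H2 = range(6)


def _hydroxyl_h(c: np.ndarray, o_carb: np.ndarray, o_h: np.ndarray, cis: bool) -> np.ndarray:
    """In-plane H position on a hydroxyl O with the requested orientation."""
    u = (o_h - c) / np.linalg.norm(o_h - c)
    normal = np.array([0.0, 0.0, 1.0])
    w = np.cross(normal, u)
    theta = np.radians(180.0 - COH_ANGLE)
    cands = [
        o_h + O_H_BOND * (np.cos(theta) * u + s * np.sin(theta) * w) for s in (1.0, -1.0)
    ]
    for cand in cands:
        ang = dihedral(o_carb, c, o_h, cand, _FREE_CELL)
        if (abs(ang) < np.pi / 2) == cis:
            return cand
    raise RuntimeError("could not realize requested hydroxyl orientation")


def solute_template(conformer: str) -> np.ndarray:
    """Planar acid geometry (6, 3) with the requested conformer.

    CC: both dihedrals cis; CT: first cis, second trans; TT: both trans.
    """
    cis = {"CC": (True, True), "CT": (True, False), "TT": (False, False)}[conformer]
    c = np.zeros(3)
    o_carb = np.array([0.0, C_O_DOUBLE, 0.0])
    ang1, ang2 = np.radians(210.0), np.radians(330.0)  # carbonyl sits at 90 deg
    o1 = C_OH_BOND * np.array([np.cos(ang1), np.sin(ang1), 0.0])
    o2 = C_OH_BOND * np.array([np.cos(ang2), np.sin(ang2), 0.0])
    h1 = _hydroxyl_h(c, o_carb, o1, cis[0])
    h2 = _hydroxyl_h(c, o_carb, o2, cis[1])
    return np.vstack([c, o_carb, o1, o2, h1, h2])


@dataclass
class GeometryTemplates:
    """Idealized internal coordinates and thermal jitter for rendering.

    Jitter is applied as a rigid per-molecule Gaussian displacement
    (sigma in Angstrom): intermolecular geometry fluctuates while internal
    coordinates — and hence the scripted labels — stay exact.
    """

    jitter: float = 0.05

    def solute(self, conformer: str) -> np.ndarray:
        return solute_template(conformer)


def _apply_jitter(
    coords: np.ndarray, mol_ids: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    offsets = rng.normal(0.0, sigma, (int(mol_ids.max()) + 1, 3))
    return coords + offsets[mol_ids]


def _water_h(o: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Two H positions for a water at o with bisector along ``axis``."""
    axis = axis / np.linalg.norm(axis)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    perp = np.cross(axis, ref)
    perp /= np.linalg.norm(perp)
    half = np.radians(WATER_ANGLE / 2)
    h1 = o + WATER_OH * (np.cos(half) * axis + np.sin(half) * perp)
    h2 = o + WATER_OH * (np.cos(half) * axis - np.sin(half) * perp)
    return np.vstack([h1, h2])


def _safe_proton_direction(host: np.ndarray, other_o: np.ndarray) -> np.ndarray:
    """Unit vector from the host O that keeps the proton far from other O."""
    if len(other_o) == 0:
        return np.array([0.0, 0.0, 1.0])
    dirs = []
    for v in ([1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
              [1, 1, 1], [-1, -1, 1], [1, -1, -1], [-1, 1, -1]):
        d = np.asarray(v, dtype=float)
        dirs.append(d / np.linalg.norm(d))
    best, best_score = dirs[0], -np.inf
    for d in dirs:
        p = host + O_H_BOND * d
        score = np.min(np.linalg.norm(other_o - p, axis=1))
        if score > best_score:
            best, best_score = d, score
    return best


@dataclass
class RenderedSystem:
    """Static scaffold shared by all frames of a rendered trajectory."""

    species: list[str]
    base_coords: np.ndarray  # solute in source conformation + waters
    cell: CellSpec
    water_o: np.ndarray  # atom indices of water oxygens
    solute_center: np.ndarray


def _place_waters(
    n_waters: int,
    box: float,
    solute: np.ndarray,
    rng: np.random.Generator,
    min_oo: float = 2.2,
) -> np.ndarray:
    """Water O sites: two H-bond partners for the hydroxyl hydrogens, the
    rest on a jittered cubic lattice clear of the solute."""
    center = np.full(3, box / 2)
    sol = solute + center
    partners = []
    for h_idx, o_idx in ((IDX_H1, IDX_O1), (IDX_H2, IDX_O2)):
        direction = sol[h_idx] - sol[o_idx]
        direction /= np.linalg.norm(direction)
        partners.append(sol[o_idx] + 2.8 * direction)
    sites = []
    n_side = max(2, int(np.floor(box / 3.1)))
    spacing = box / n_side
    for i in range(n_side):
        for j in range(n_side):
            for k in range(n_side):
                sites.append(spacing * (np.array([i, j, k]) + 0.5))
    sites = np.array(sites)
    order = rng.permutation(len(sites))
    chosen = list(partners[: min(2, n_waters)])
    for idx in order:
        if len(chosen) >= n_waters:
            break
        cand = sites[idx] + rng.normal(0, 0.1, 3)
        d_sol = np.min(np.linalg.norm(sol - cand, axis=1))
        d_wat = min((np.linalg.norm(c - cand) for c in chosen), default=np.inf)
        if d_sol >= 2.5 and d_wat >= 2.9:
            chosen.append(cand)
    if len(chosen) < n_waters:
        raise PackingError(
            f"could only place {len(chosen)} of {n_waters} waters in a {box} A box"
        )
    waters = np.array(chosen)
    dmat = np.linalg.norm(waters[:, None] - waters[None, :], axis=-1)
    np.fill_diagonal(dmat, np.inf)
    if dmat.min() < min_oo or np.min(
        np.linalg.norm(sol[[IDX_OC, IDX_O1, IDX_O2]][:, None] - waters[None], axis=-1)
    ) < min_oo:
        raise PackingError("intermolecular O-O contact below safe separation")
    return waters


def _build_system(
    source: str,
    n_waters: int,
    box: float,
    rng: np.random.Generator,
) -> RenderedSystem:
    center = np.full(3, box / 2)
    solute = solute_template(source)
    waters_o = _place_waters(n_waters, box, solute, rng)
    species = list(SOLUTE_ATOMS)
    coords = [solute + center]
    water_o_idx = []
    for w in waters_o:
        axis = w - center
        h = _water_h(w, axis)
        water_o_idx.append(len(species))
        species.extend(["O", "H", "H"])
        coords.append(np.vstack([w, h]))
    return RenderedSystem(
        species=species,
        base_coords=np.vstack(coords),
        cell=CellSpec((box, box, box)),
        water_o=np.array(water_o_idx),
        solute_center=center,
    )


# ---------------------------------------------------------------------------
# atomistic rendering
# ---------------------------------------------------------------------------

def render_atomistic(
    scripts_or_stateseq,
    templates: GeometryTemplates | None = None,
    n_waters: int = 12,
    box: float = 12.44,
    seed: int = 0,
    dt: float = 0.1,
) -> tuple[Trajectory, dict]:
    """Render episode scripts or a label sequence into coordinates.

    Returns the trajectory and a ground-truth log (events, labels,
    parameters, seed).  At zero jitter the rendered trajectory reproduces
    the scripted labels exactly under the topology pipeline.
    """
    templates = templates or GeometryTemplates()
    if isinstance(scripts_or_stateseq, StateSequence):
        return _render_state_sequence(
            scripts_or_stateseq, templates, n_waters, box, seed, dt
        )
    return _render_episodes(list(scripts_or_stateseq), templates, n_waters, box, seed, dt)


def _render_episodes(
    scripts: list[EpisodeScript],
    templates: GeometryTemplates,
    n_waters: int,
    box: float,
    seed: int,
    dt: float,
    pre_frames: int = 3,
    post_frames: int = 2,
) -> tuple[Trajectory, dict]:
    rng = np.random.default_rng(seed)
    systems = {
        s: _build_system(s, n_waters, box, np.random.default_rng(seed + 17 * (i + 1)))
        for i, s in enumerate(sorted({sc.source for sc in scripts}))
    }
    frames: list[np.ndarray] = []
    species_ref: list[str] | None = None
    events = []
    t_index = 0
    for sc in scripts:
        sys_ = systems[sc.source]
        if species_ref is None:
            species_ref = sys_.species
        base = sys_.base_coords
        o_all = np.array([i for i, s in enumerate(sys_.species) if s == "O"])
        # per-episode host schedule: origin hydroxyl O1 loses H1
        origin_atom = IDX_O1
        landing_atom = IDX_O1 if sc.endpoint == "homing" else IDX_OC
        schedule: list[int | None] = [None] * pre_frames  # None = proton at home
        chain_positions: list[list[int]] = [
            [w] * sc.hold_frames for w in sc.hosts
        ]
        for pos, other in sc.rattles:
            # one-frame excursion; both flanking sub-segments stay >= 2
            # frames so the rattle filters out without touching real hops
            chain_positions[pos].insert(2, other)
            chain_positions[pos].append(sc.hosts[pos])
        for pos_frames in chain_positions:
            schedule.extend(pos_frames)
        schedule.extend(["land"] * post_frames)
        mol_ids = _molecule_ids(sys_)
        t_start = None
        for entry in schedule:
            coords = base.copy()
            mols = mol_ids.copy()
            if entry is None:
                pass  # intact source conformer
            elif entry == "land":
                coords[IDX_H1] = _land_proton(sys_, landing_atom)
            else:
                host_atom = int(sys_.water_o[entry])
                other_o = np.delete(coords[o_all], np.flatnonzero(o_all == host_atom), axis=0)
                d = _safe_proton_direction(coords[host_atom], other_o)
                coords[IDX_H1] = coords[host_atom] + O_H_BOND * d
                mols[IDX_H1] = mols[host_atom]  # proton rides with its host
                if t_start is None:
                    t_start = t_index * dt
            if templates.jitter > 0:
                coords = _apply_jitter(coords, mols, templates.jitter, rng)
            frames.append(coords)
            t_index += 1
        events.append(
            {
                "source": sc.source,
                "n_hops": sc.n_hops,
                "endpoint": sc.endpoint,
                "n_rattles": len(sc.rattles),
                "t_start_ps": t_start,
            }
        )
    coords_arr = np.stack(frames)
    traj = Trajectory(species_ref, coords_arr, CellSpec((box, box, box)), dt=dt)
    truth = ground_truth_summary(scripts)
    truth.update({"seed": seed, "n_waters": n_waters, "box_A": box, "dt_ps": dt,
                  "events": events})
    return traj, truth


def _molecule_ids(sys_: RenderedSystem) -> np.ndarray:
    """Molecule index per atom: solute 0, waters 1..n in order."""
    ids = np.zeros(len(sys_.species), dtype=int)
    for w, o_atom in enumerate(sys_.water_o):
        ids[o_atom : o_atom + 3] = w + 1
    return ids


def _land_proton(sys_: RenderedSystem, landing_atom: int) -> np.ndarray:
    """Proton position on the landing carboxyl oxygen (in-plane, outward)."""
    o = sys_.base_coords[landing_atom]
    c = sys_.base_coords[IDX_C]
    u = (o - c) / np.linalg.norm(o - c)
    normal = np.array([0.0, 0.0, 1.0])
    w = np.cross(normal, u)
    theta = np.radians(180.0 - COH_ANGLE)
    return o + O_H_BOND * (np.cos(theta) * u + np.sin(theta) * w)


def _render_state_sequence(
    seq: StateSequence,
    templates: GeometryTemplates,
    n_waters: int,
    box: float,
    seed: int,
    dt: float,
) -> tuple[Trajectory, dict]:
    """Realize a conformer/species label sequence as coordinates.

    Conformer changes are instant template switches; HCO3 frames park the
    second acid proton on the first water (hydronium), CO3 frames park both.
    """
    rng = np.random.default_rng(seed)
    sys_ = _build_system("CC", n_waters, box, np.random.default_rng(seed + 17))
    center = sys_.solute_center
    o_all = np.array([i for i, s in enumerate(sys_.species) if s == "O"])
    solute_cache = {
        c: solute_template(c) + center for c in ("CC", "CT", "TT")
    }
    mol_ids = _molecule_ids(sys_)
    frames = []
    for lab in seq.labels:
        coords = sys_.base_coords.copy()
        mols = mol_ids.copy()
        if lab.startswith("H2CO3_"):
            coords[:6] = solute_cache[lab.split("_")[-1]]
        elif lab in ("HCO3", "CO3"):
            coords[:6] = solute_cache["CC"]
            for k, h_idx in enumerate([IDX_H2] if lab == "HCO3" else [IDX_H1, IDX_H2]):
                host_atom = int(sys_.water_o[k])
                other_o = np.delete(
                    coords[o_all], np.flatnonzero(o_all == host_atom), axis=0
                )
                d = _safe_proton_direction(coords[host_atom], other_o)
                coords[h_idx] = coords[host_atom] + O_H_BOND * d
                mols[h_idx] = mols[host_atom]
        else:
            raise ValueError(f"cannot render label {lab!r}")
        if templates.jitter > 0:
            coords = _apply_jitter(coords, mols, templates.jitter, rng)
        frames.append(coords)
    traj = Trajectory(sys_.species, np.stack(frames), sys_.cell, dt=dt)
    truth = {
        "seed": seed,
        "labels": list(seq.labels),
        "n_waters": n_waters,
        "box_A": box,
        "dt_ps": dt,
    }
    return traj, truth


# ---------------------------------------------------------------------------
# reference free-energy profiles and Boltzmann sampling
# ---------------------------------------------------------------------------

def reference_profile_values(params: dict, n: np.ndarray) -> np.ndarray:
    """Analytic reference dissociation profile evaluated at ``n``.

    A flat-topped (super-Gaussian) barrier between the protonated basin at
    n ~ 1 and the deprotonated side, a linear tilt keeping the global
    minimum protonated, and a harmonic wall beyond the basin.  The overall
    amplitude is rescaled so that the barrier read-off on the analysis grid
    equals ``barrier_kcal_mol`` exactly.
    """
    n = np.asarray(n, dtype=float)
    shape = _profile_shape(params, n)
    if not params.get("rescale", True):
        return float(params["barrier_kcal_mol"]) * shape
    return _profile_scale(params) * shape


def _profile_shape(params: dict, n: np.ndarray) -> np.ndarray:
    nb = params.get("barrier_center", 0.45)
    sigma = params.get("barrier_sigma", 0.15)
    tilt = params.get("tilt", 0.8)
    wall_k = params.get("wall_k", 40.0)
    wall_edge = params.get("wall_edge", 1.1)
    z = (n - nb) ** 2 / (2 * sigma**2)
    bump = np.exp(-(z**2))  # flat-topped barrier: zero curvature at the max
    out = bump + tilt * np.clip(1.0 - n, 0.0, None)
    out = out + wall_k * np.clip(n - wall_edge, 0.0, None) ** 2
    return out


def _profile_scale(params: dict) -> float:
    target = float(params["barrier_kcal_mol"])
    bins = int(params.get("bins", 100))
    lo, hi = params.get("range", (0.0, 2.5))
    edges = np.linspace(lo, hi, bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2
    shape = _profile_shape(params, centers)
    prof = FreeEnergyProfile(centers=centers, F=shape - shape.min(), kT=1.0)
    raw = dissociation_delta_f(prof)
    return target / raw


def reference_profile(params: dict) -> FreeEnergyProfile:
    """Reference profile tabulated on the analysis grid."""
    bins = int(params.get("bins", 100))
    lo, hi = params.get("range", (0.0, 2.5))
    edges = np.linspace(lo, hi, bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2
    F = reference_profile_values(params, centers)
    return FreeEnergyProfile(centers=centers, F=F - F.min(), kT=kT_at())


def sample_coordination(
    profile_params: dict,
    kT: float,
    n: int,
    seed: int,
    grid_points: int = 4000,
) -> np.ndarray:
    """i.i.d. coordination samples from density prop. to exp(-F_ref/kT).

    Inverse-CDF sampling on a fine grid over the profile's range.
    """
    rng = np.random.default_rng(seed)
    lo, hi = profile_params.get("range", (0.0, 2.5))
    grid = np.linspace(lo, hi, grid_points)
    F = reference_profile_values(profile_params, grid)
    w = np.exp(-(F - F.min()) / kT)
    cdf = np.cumsum(w)
    cdf = cdf / cdf[-1]
    u = rng.random(n)
    return np.interp(u, cdf, grid)


# ---------------------------------------------------------------------------
# label-sequence motifs for transition statistics
# ---------------------------------------------------------------------------

def generate_transition_motifs(
    n_motifs: int,
    p_indirect: float,
    seed: int,
    run_frames: int = 3,
    dt: float = 0.1,
) -> tuple[StateSequence, dict]:
    """CT -> CC transition motifs, a fraction passing through bicarbonate."""
    rng = np.random.default_rng(seed)
    labels: list[str] = []
    n_indirect = 0
    for _ in range(n_motifs):
        labels.extend(["H2CO3_CT"] * run_frames)
        if rng.random() < p_indirect:
            labels.extend(["HCO3"] * run_frames)
            n_indirect += 1
        labels.extend(["H2CO3_CC"] * run_frames)
    seq = StateSequence(
        labels=labels,
        dihedrals=np.full((len(labels), 2), np.nan),
        times=np.arange(len(labels)) * dt,
    )
    truth = {
        "n_motifs": n_motifs,
        "indirect_pct": 100.0 * n_indirect / n_motifs,
        "seed": seed,
    }
    return seq, truth


# ---------------------------------------------------------------------------
# RDF shell fixture rendering
# ---------------------------------------------------------------------------

def render_shell_frames(params: dict, seed: int) -> tuple[Trajectory, dict]:
    """Frames with water oxygens in a Gaussian radial shell around the
    carbonyl oxygen, for RDF estimator recovery."""
    rng = np.random.default_rng(seed)
    box = float(params.get("box_A", 12.44))
    radius = float(params["radius_A"])
    sigma = float(params.get("sigma_A", 0.1))
    n_o = int(params.get("n_oxygens", 8))
    n_frames = int(params.get("n_frames", 2000))
    center = np.full(3, box / 2)
    solute = solute_template("CC") + center
    species = SOLUTE_ATOMS + ["O"] * n_o
    frames = np.empty((n_frames, len(species), 3))
    for i in range(n_frames):
        coords = solute.copy()
        r = rng.normal(radius, sigma, n_o)
        v = rng.normal(size=(n_o, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        shell = solute[IDX_OC] + r[:, None] * v
        frames[i] = np.vstack([coords, shell])
    traj = Trajectory(species, frames, CellSpec((box, box, box)), dt=1.0)
    truth = {"radius_A": radius, "sigma_A": sigma, "n_oxygens": n_o,
             "n_frames": n_frames, "seed": seed, "carbonyl_index": IDX_OC,
             "shell_indices": list(range(6, 6 + n_o))}
    return traj, truth


# ---------------------------------------------------------------------------
# calibration fixtures
# ---------------------------------------------------------------------------

#: canonical fixture contents; `paper_calibration_fixtures` writes these.
FIXTURES: dict[str, dict] = {
    "markov_paper.yaml": {
        "states": ["H2CO3_CC", "H2CO3_CT", "H2CO3_TT", "HCO3", "CO3"],
        "stationary": [0.813, 0.124, 0.003, 0.05995, 0.00005],
        "flows": [
            ["H2CO3_CC", "H2CO3_CT", 0.02],
            ["H2CO3_CT", "H2CO3_TT", 0.004],
            ["H2CO3_CC", "HCO3", 0.01],
            ["H2CO3_CT", "HCO3", 0.01],
            ["HCO3", "CO3", 2.0e-04],
        ],
        "dt_ps": 0.1,
        "co3_bound_pct": 0.01,
    },
    "episodes_paper.yaml": {
        "source_weights": {"CT": 0.581, "CC": 0.419},
        "hop_distribution": {2: 0.65, 3: 0.15, 4: 0.09, 5: 0.05, 6: 0.03,
                             7: 0.015, 8: 0.01, 9: 0.005},
        "endpoint_probs": {"CT": {"homing": 0.8295}, "CC": {"homing": 0.5776}},
        "rattle_rate": 0.3,
        "n_waters": 12,
        "box_A": 12.44,
        "dt_ps": 0.1,
    },
    "profile_cc.yaml": {
        "barrier_kcal_mol": 7.43,
        "barrier_center": 0.45,
        "barrier_sigma": 0.15,
        "tilt": 0.8,
        "wall_k": 40.0,
        "wall_edge": 1.1,
        "range": [0.0, 2.5],
        "bins": 100,
        "temperature_K": 330.0,
        "n_samples": 20000000,
    },
    "profile_ct.yaml": {
        "barrier_kcal_mol": 4.31,
        "barrier_center": 0.45,
        "barrier_sigma": 0.15,
        "tilt": 0.8,
        "wall_k": 40.0,
        "wall_edge": 1.1,
        "range": [0.0, 2.5],
        "bins": 100,
        "temperature_K": 330.0,
        "n_samples": 20000000,
    },
    "transitions_paper.yaml": {
        "p_indirect": 0.8902,
        "n_motifs": 5000,
        "run_frames": 3,
    },
    "rdf_shell.yaml": {
        "radius_A": 2.83,
        "sigma_A": 0.1,
        "n_oxygens": 8,
        "n_frames": 2000,
        "box_A": 12.44,
        "dr_A": 0.02,
    },
}


def paper_calibration_fixtures(out_dir: str | Path) -> list[Path]:
    """Write the calibration fixture configs to ``out_dir``; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, content in FIXTURES.items():
        p = out_dir / name
        with open(p, "w") as fh:
            yaml.safe_dump(content, fh, sort_keys=False)
        paths.append(p)
    return paths


def load_fixture(name: str) -> dict:
    """Load a packaged calibration fixture by file name."""
    res = importlib.resources.files("carbodyn") / "fixtures" / name
    with res.open() as fh:
        return yaml.safe_load(fh)


def markov_model_from_fixture(fx: dict) -> MarkovModel:
    return MarkovModel.from_stationary(
        states=fx["states"],
        stationary=fx["stationary"],
        flows=[tuple(f) for f in fx["flows"]],
        dt=float(fx["dt_ps"]),
    )
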