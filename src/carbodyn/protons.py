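"""Proton-transfer detection: host tracking, rattling filter, episodes.

A dissociation episode runs from an accepted deprotonation of the acid to the
accepted reprotonation of any of its carboxyl oxygens.  The dissociated
proton (tracked as the protonic defect, i.e. the oxygen carrying the excess
hydrogen) hops through the water network; rapid back-and-forth exchanges
("rattling") are removed by a minimum-residence filter before hops are
counted.  By convention the dissociation and the recombination each count as
one hop, so the minimal completed episode — proton out to the nearest water
and straight back — has two hops ("short-range" transfer); everything longer
is "long-range".  Episodes are classified by endpoint: *homing* (proton
returns to the originally deprotonated hydroxyl oxygen), *exploratory*
(proton binds another carboxyl oxygen of the same carbon) or *escaped*
(still outstanding at trajectory end).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from carbodyn.io import Trajectory
from carbodyn.topology import (
    CONFORMER_LABELS,
    BondMap,
    StateSequence,
    assign_hydrogens,
)

logger = logging.getLogger(__name__)

#: minimum residence time (ps) for a host interval to count as committed.
TAU_COMMIT = 0.2
#: maximum gap (ps) between hops sharing an intermediate O to be concerted.
TAU_CONCERT = 0.1


@dataclass(frozen=True)
class HostRecord:
    """Host oxygen of the tracked proton at one frame."""

    time: float
    proton: int
    host: int


@dataclass
class HostInterval:
    """Maximal stretch of frames with a constant host oxygen."""

    host: int
    t0: float
    t1: float  # may be +/- inf for chain-terminal acid intervals
    associated: bool = False  # acid holds the proton during this interval

    @property
    def duration(self) -> float:
        return self.t1 - self.t0


@dataclass(frozen=True)
class HopEvent:
    """One accepted host change of the tracked proton."""

    time: float
    proton: int
    from_o: int
    to_o: int
    concerted_group: int | None = None


@dataclass
class DissociationEpisode:
    """One dissociation -> (hops) -> recombination arc."""

    source_conformer: str  # CC / CT / TT / unknown
    origin_o: int
    hops: list[HopEvent]
    n_hops: int
    range_class: str  # short / long
    endpoint: str  # homing / exploratory / escaped
    t_start: float
    t_end: float
    overlapping: bool = False

    @property
    def n_concerted_groups(self) -> int:
        groups = {h.concerted_group for h in self.hops if h.concerted_group is not None}
        return len(groups)


@dataclass(frozen=True)
class TransitionEvent:
    """Conformer interconversion, direct or via a bicarbonate intermediate."""

    kind: str  # direct / indirect
    from_label: str
    to_label: str
    t: float


@dataclass
class RawArc:
    """Unfiltered dissociation arc as tracked frame by frame."""

    origin_o: int
    records: list[HostRecord]
    landing_o: int | None
    t_diss: float  # time of the first dissociated frame
    t_land: float | None  # time of the recombined frame (None = escaped)
    overlapping: bool = False
    proton: int = -1


# ---------------------------------------------------------------------------
# host tracking
# ---------------------------------------------------------------------------

def track_hosts(
    traj: Trajectory,
    bondmaps: Sequence[BondMap],
    stateseq: StateSequence,
) -> list[RawArc]:
    """Follow the dissociated proton through the oxygen network.

    While the acid is doubly protonated nothing is recorded; from each
    deprotonation the excess-proton host (the non-acid oxygen with three
    hydrogens) is followed until recombination or trajectory end.  Arcs
    during which the acid loses both protons are flagged ``overlapping`` and
    later excluded from single-proton statistics.
    """
    acid_o = set(stateseq.acid_oxygens)
    if not acid_o:
        raise ValueError("state sequence carries no acid oxygen indices")
    arcs: list[RawArc] = []
    current: RawArc | None = None
    prev_bm: BondMap | None = None
    prev_host: int | None = None
    for i in range(len(traj)):
        bm = bondmaps[i]
        t = float(stateseq.times[i])
        acid_h = sum(bm.o_h_count[o] for o in acid_o)
        if acid_h >= 2:
            if current is not None:  # recombination
                landings = [
                    o for o in acid_o
                    if prev_bm is not None and bm.o_h_count[o] > prev_bm.o_h_count[o]
                ]
                landing = landings[0] if landings else current.origin_o
                current.records.append(HostRecord(t, current.proton, landing))
                current.landing_o = int(landing)
                current.t_land = t
                arcs.append(current)
                current = None
                prev_host = None
        else:
            if current is None:  # deprotonation
                origins = [
                    o for o in acid_o
                    if prev_bm is not None and bm.o_h_count[o] < prev_bm.o_h_count[o]
                ]
                origin = origins[0] if origins else next(iter(acid_o))
                proton = -1
                if prev_bm is not None:
                    for h, o in prev_bm.h_to_o.items():
                        if o == origin and bm.h_to_o.get(h) != origin:
                            proton = h
                            break
                t_prev = float(stateseq.times[i - 1]) if i > 0 else t - traj.dt
                current = RawArc(
                    origin_o=int(origin),
                    records=[HostRecord(t_prev, proton, int(origin))],
                    landing_o=None,
                    t_diss=t,
                    t_land=None,
                    proton=proton,
                )
                prev_host = int(origin)
            host = _defect_host(bm, acid_o, prev_host)
            if host is not None and host != prev_host:
                # identify the H that arrived on the new host this frame
                for h, o in bm.h_to_o.items():
                    if o == host and (prev_bm is None or prev_bm.h_to_o.get(h) != host):
                        current.proton = h
                        break
            if host is not None:
                current.records.append(HostRecord(t, current.proton, host))
                prev_host = host
            if acid_h == 0:
                current.overlapping = True
        prev_bm = bm
    if current is not None:  # escaped
        arcs.append(current)
    return arcs


def _defect_host(bm: BondMap, acid_o: set[int], prev_host: int | None) -> int | None:
    """The oxygen carrying the excess proton (hydronium)."""
    candidates = [o for o, n in bm.o_h_count.items() if o not in acid_o and n >= 3]
    if len(candidates) == 1:
        return candidates[0]
    if len(candidates) > 1:
        if prev_host in candidates:
            return prev_host
        return candidates[0]
    return prev_host  # transient mid-hop frame: keep previous assignment


# ---------------------------------------------------------------------------
# rattling filter
# ---------------------------------------------------------------------------

def _merge_equal(intervals: list[HostInterval]) -> list[HostInterval]:
    out: list[HostInterval] = []
    for iv in intervals:
        if out and out[-1].host == iv.host:
            out[-1] = HostInterval(out[-1].host, out[-1].t0, iv.t1,
                                   out[-1].associated or iv.associated)
        else:
            out.append(replace(iv))
    return out


def filter_rattling(
    intervals: Sequence[HostInterval],
    tau_commit: float = TAU_COMMIT,
    collapse_mediated: bool = False,
) -> list[HostInterval]:
    """Minimum-residence compression of a host-interval series.

    Contiguous blocks of interior intervals shorter than ``tau_commit``
    whose two flanking hosts coincide are rattling: the block is deleted
    and its duration absorbed into the merged flank.  Blocks are removed
    deterministically — largest block first, leftmost on ties — and the
    rule is iterated to a fixed point.  Sub-threshold stretches that
    survive (their flanks differ) mediate a net host change and are
    retained, or collapsed to a direct flank-to-flank hop when
    ``collapse_mediated`` is true.  The first and last intervals are
    terminal and never deleted.
    """
    if tau_commit < 0:
        raise ValueError("tau_commit must be >= 0")
    series = _merge_equal(list(intervals))
    if tau_commit == 0:
        return series
    changed = True
    while changed:
        changed = False
        n = len(series)
        if n < 3:
            break
        # small tolerance so an interval of exactly tau_commit built from
        # accumulated frame times never misclassifies as sub-threshold
        sub = [
            0 < i < n - 1 and series[i].duration < tau_commit - 1e-9
            for i in range(n)
        ]
        for start, width in _blocks_by_priority(sub):
            left, right = series[start - 1], series[start + width]
            if left.host == right.host:
                merged = HostInterval(left.host, left.t0, right.t1,
                                      left.associated or right.associated)
                series = series[: start - 1] + [merged] + series[start + width + 1:]
                changed = True
                break
        if not changed and collapse_mediated:
            for start, width in _blocks_by_priority(sub):
                if width < 1:
                    continue
                # maximal block only: flanks are committed hosts
                if (start > 1 and sub[start - 1]) or (
                    start + width < n - 1 and sub[start + width]
                ):
                    continue
                left = series[start - 1]
                left2 = HostInterval(left.host, left.t0, series[start + width - 1].t1,
                                     left.associated)
                series = series[: start - 1] + [left2] + series[start + width:]
                changed = True
                break
        series = _merge_equal(series)
    return series


def _blocks_by_priority(sub: list[bool]) -> list[tuple[int, int]]:
    """All contiguous sub-threshold blocks as (start, width), largest
    first, leftmost on ties."""
    n = len(sub)
    blocks = []
    for start in range(1, n - 1):
        if not sub[start]:
            continue
        width = 0
        while start + width < n - 1 and sub[start + width]:
            width += 1
        for w in range(1, width + 1):
            blocks.append((start, w))
    blocks.sort(key=lambda b: (-b[1], b[0]))
    return blocks


def extract_hops(intervals: Sequence[HostInterval], proton: int = -1) -> list[HopEvent]:
    """One hop per host change in a (filtered) interval series.

    Boundaries between two associated acid intervals (the proton never left)
    produce no hop.
    """
    hops: list[HopEvent] = []
    for prev, cur in zip(intervals, intervals[1:]):
        if prev.host == cur.host:
            continue
        if prev.associated and cur.associated:
            continue
        hops.append(HopEvent(time=cur.t0, proton=proton, from_o=prev.host, to_o=cur.host))
    return hops


def mark_concerted(hops: Sequence[HopEvent], tau_concert: float = TAU_CONCERT) -> list[HopEvent]:
    """Group consecutive hops closer than ``tau_concert`` that share an
    intermediate oxygen; grouping is transitive along a chain."""
    if tau_concert <= 0:
        raise ValueError("tau_concert must be > 0")
    out = [replace(h) for h in hops]
    group_id = 0
    i = 0
    n = len(out)
    while i < n - 1:
        j = i
        while (
            j + 1 < n
            and out[j + 1].time - out[j].time < tau_concert
            and out[j].to_o == out[j + 1].from_o
        ):
            j += 1
        if j > i:
            for k in range(i, j + 1):
                out[k] = replace(out[k], concerted_group=group_id)
            group_id += 1
        i = j + 1
    return out


# ---------------------------------------------------------------------------
# episode segmentation and classification
# ---------------------------------------------------------------------------

def _source_conformer(stateseq: StateSequence, t_start: float) -> str:
    idx = int(np.searchsorted(stateseq.times, t_start, side="left")) - 1
    while idx >= 0:
        lab = stateseq.labels[idx]
        if lab in CONFORMER_LABELS:
            return lab.split("_")[-1]
        idx -= 1
    return "unknown"


def segment_episodes(
    hops: Sequence[HopEvent],
    stateseq: StateSequence,
    acid_oxygens: Sequence[int] | None = None,
) -> list[DissociationEpisode]:
    """Cut an accepted-hop list into dissociation episodes.

    An episode opens at a hop leaving an acid oxygen and closes at the first
    hop landing on any carboxyl oxygen of the same carbon; an unclosed
    episode at trajectory end is ``escaped``.
    """
    acid_o = set(acid_oxygens if acid_oxygens is not None else stateseq.acid_oxygens)
    episodes: list[DissociationEpisode] = []
    open_hops: list[HopEvent] = []
    origin: int | None = None
    for hop in hops:
        if origin is None:
            if hop.from_o in acid_o:
                origin = hop.from_o
                open_hops = [hop]
            continue
        open_hops.append(hop)
        if hop.to_o in acid_o:
            endpoint = "homing" if hop.to_o == origin else "exploratory"
            episodes.append(
                DissociationEpisode(
                    source_conformer=_source_conformer(stateseq, open_hops[0].time),
                    origin_o=origin,
                    hops=open_hops,
                    n_hops=len(open_hops),
                    range_class="short" if len(open_hops) == 2 else "long",
                    endpoint=endpoint,
                    t_start=open_hops[0].time,
                    t_end=hop.time,
                )
            )
            origin = None
            open_hops = []
    if origin is not None and open_hops:
        episodes.append(
            DissociationEpisode(
                source_conformer=_source_conformer(stateseq, open_hops[0].time),
                origin_o=origin,
                hops=open_hops,
                n_hops=len(open_hops),
                range_class="long",
                endpoint="escaped",
                t_start=open_hops[0].time,
                t_end=open_hops[-1].time,
            )
        )
    return episodes


def classify_transitions(stateseq: StateSequence) -> list[TransitionEvent]:
    """Direct vs indirect conformer transitions.

    Successive distinct conformer labels produce one event; the transition
    is *indirect* when a bicarbonate (or carbonate) interval separates them,
    *direct* when the labels are adjacent in time.
    """
    runs: list[tuple[str, int]] = []
    for i, lab in enumerate(stateseq.labels):
        if not runs or runs[-1][0] != lab:
            runs.append((lab, i))
    events: list[TransitionEvent] = []
    prev_conf: tuple[str, int] | None = None
    saw_intermediate = False
    for lab, start in runs:
        if lab in CONFORMER_LABELS:
            if prev_conf is not None and lab != prev_conf[0]:
                events.append(
                    TransitionEvent(
                        kind="indirect" if saw_intermediate else "direct",
                        from_label=prev_conf[0],
                        to_label=lab,
                        t=float(stateseq.times[start]),
                    )
                )
            prev_conf = (lab, start)
            saw_intermediate = False
        elif lab in ("HCO3", "CO3"):
            saw_intermediate = True
    return events


def transition_fraction_indirect(
    events: Sequence[TransitionEvent],
    from_label: str = "H2CO3_CT",
    to_label: str = "H2CO3_CC",
) -> float:
    """Percentage of from->to transitions that pass through bicarbonate."""
    sel = [e for e in events if e.from_label == from_label and e.to_label == to_label]
    if not sel:
        raise ValueError(f"no {from_label}->{to_label} transitions found")
    return 100.0 * sum(e.kind == "indirect" for e in sel) / len(sel)


def episode_statistics(
    episodes: Sequence[DissociationEpisode],
    weight: str = "episodes",
) -> dict:
    """Summary statistics over completed, non-overlapping episodes.

    Returns the hop-count histogram per source conformer, the proton-source
    fractions (percent of episodes, or of hops when ``weight='hops'``), and
    the homing fraction per source conformer.
    """
    completed = [
        e for e in episodes if e.endpoint in ("homing", "exploratory") and not e.overlapping
    ]
    if not completed:
        logger.warning("no completed episodes; returning empty summary")
        return {
            "n_completed": 0,
            "hop_histogram": {},
            "source_fraction_pct": {},
            "homing_fraction_pct": {},
            "short_range_pct": float("nan"),
        }
    hist: dict[str, dict[int, int]] = {}
    for e in completed:
        hist.setdefault(e.source_conformer, {})
        hist[e.source_conformer][e.n_hops] = hist[e.source_conformer].get(e.n_hops, 0) + 1
    if weight == "hops":
        tot = sum(e.n_hops for e in completed)
        source = {
            s: 100.0 * sum(e.n_hops for e in completed if e.source_conformer == s) / tot
            for s in hist
        }
    else:
        source = {
            s: 100.0 * sum(e.source_conformer == s for e in completed) / len(completed)
            for s in hist
        }
    homing = {}
    for s in hist:
        mine = [e for e in completed if e.source_conformer == s]
        homing[s] = 100.0 * sum(e.endpoint == "homing" for e in mine) / len(mine)
    return {
        "n_completed": len(completed),
        "hop_histogram": {s: dict(sorted(d.items())) for s, d in sorted(hist.items())},
        "source_fraction_pct": dict(sorted(source.items())),
        "homing_fraction_pct": dict(sorted(homing.items())),
        "short_range_pct": 100.0 * sum(e.n_hops == 2 for e in completed) / len(completed),
    }


# ---------------------------------------------------------------------------
# end-to-end analysis
# ---------------------------------------------------------------------------

@dataclass
class ProtonAnalysis:
    episodes: list[DissociationEpisode]
    hops: list[HopEvent]
    transitions: list[TransitionEvent]
    statistics: dict

    def episodes_to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            {
                "t_start_ps": [e.t_start for e in self.episodes],
                "t_end_ps": [e.t_end for e in self.episodes],
                "source": [e.source_conformer for e in self.episodes],
                "n_hops": [e.n_hops for e in self.episodes],
                "range": [e.range_class for e in self.episodes],
                "endpoint": [e.endpoint for e in self.episodes],
                "n_concerted_groups": [e.n_concerted_groups for e in self.episodes],
            }
        )
        df.to_csv(path, sep="\t", index=False)


def arcs_to_interval_chains(
    arcs: Sequence[RawArc],
    dt: float,
    tau_commit: float = TAU_COMMIT,
) -> list[tuple[list[HostInterval], bool]]:
    """Convert raw arcs to host-interval chains ready for filtering.

    Consecutive arcs separated by an associated gap shorter than
    ``tau_commit`` whose landing and next origin oxygen coincide are merged
    into one chain, so a sub-threshold recombination mid-episode is treated
    as rattling.  Chain-terminal acid intervals get infinite extent (they
    are exempt from the minimum-residence rule anyway).  Returns
    ``(intervals, overlapping)`` pairs.
    """
    chains: list[tuple[list[HostInterval], bool]] = []
    cur: list[HostInterval] | None = None
    cur_overlap = False

    def water_intervals(arc: RawArc) -> list[HostInterval]:
        recs = [r for r in arc.records if r.time >= arc.t_diss and
                (arc.t_land is None or r.time < arc.t_land)]
        out: list[HostInterval] = []
        for r in recs:
            if out and out[-1].host == r.host:
                out[-1].t1 = r.time + dt
            else:
                out.append(HostInterval(r.host, r.time, r.time + dt))
        return out

    for arc in arcs:
        waters = water_intervals(arc)
        if not waters:
            continue
        stitched = (
            cur is not None
            and cur[-1].associated
            and cur[-1].host == arc.origin_o
            and arc.t_diss - cur[-1].t0 < tau_commit
        )
        if stitched:
            cur[-1].t1 = waters[0].t0
        else:
            if cur is not None:
                cur[-1].t1 = math.inf
                chains.append((cur, cur_overlap))
            cur = [HostInterval(arc.origin_o, -math.inf, waters[0].t0, associated=True)]
            cur_overlap = False
        cur.extend(waters)
        cur_overlap = cur_overlap or arc.overlapping
        if arc.landing_o is not None:
            cur.append(HostInterval(arc.landing_o, arc.t_land, arc.t_land + dt,
                                    associated=True))
        else:
            chains.append((cur, cur_overlap))
            cur = None
            cur_overlap = False
    if cur is not None:
        cur[-1].t1 = math.inf
        chains.append((cur, cur_overlap))
    return chains


def analyze_protons(
    traj: Trajectory,
    stateseq: StateSequence | None = None,
    bondmaps: Sequence[BondMap] | None = None,
    tau_commit: float = TAU_COMMIT,
    tau_concert: float = TAU_CONCERT,
    collapse_mediated: bool = False,
) -> ProtonAnalysis:
    """Full proton-transfer pipeline on a labeled trajectory."""
    from carbodyn.topology import label_trajectory

    if bondmaps is None:
        bondmaps = [assign_hydrogens(f) for f in traj]
    if stateseq is None:
        stateseq = label_trajectory(traj, bondmaps=bondmaps)
    arcs = track_hosts(traj, bondmaps, stateseq)
    chains = arcs_to_interval_chains(arcs, traj.dt, tau_commit)
    all_hops: list[HopEvent] = []
    overlap_windows: list[tuple[float, float]] = []
    for intervals, overlapping in chains:
        filtered = filter_rattling(intervals, tau_commit, collapse_mediated)
        hops = extract_hops(filtered)
        if overlapping and hops:
            overlap_windows.append((hops[0].time, hops[-1].time))
        all_hops.extend(hops)
    all_hops.sort(key=lambda h: h.time)
    all_hops = mark_concerted(all_hops, tau_concert)
    episodes = segment_episodes(all_hops, stateseq)
    for e in episodes:
        for w0, w1 in overlap_windows:
            if e.t_start <= w1 and e.t_end >= w0:
                e.overlapping = True
    transitions = classify_transitions(stateseq)
    stats = episode_statistics(episodes) if episodes else episode_statistics([])
    return ProtonAnalysis(
        episodes=episodes, hops=all_hops, transitions=transitions, statistics=stats
    )
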