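"""Histogram observables: RDFs, coordination numbers, free-energy profiles.

Free energies are plain negative-log histogram estimates from unbiased
sampling, F = -kT ln p, min-subtracted.  The deprotonation reaction
coordinate is the smooth hydrogen coordination number of an oxygen,

    n(O) = sum_H [1 - (r/r0)^p] / [1 - (r/r0)^q],

a rational switching function with r0 = 1.32 A, p = 6, q = 12 by default:
close to 1 per covalently bound H, decaying smoothly to 0 with distance.
The dissociation free energy is read off a 1D profile over n as the height
of the first local maximum encountered walking from the protonated basin
(global minimum, n near 1) toward n = 0, on a 5-bin smoothed profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from carbodyn.constants import kT as kT_at
from carbodyn.io import CellSpec, Frame, Trajectory, min_image_displacements

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# radial distribution functions
# ---------------------------------------------------------------------------

@dataclass
class RDFResult:
    r: np.ndarray  # bin centers, Angstrom
    g: np.ndarray
    pair: tuple[str, str]
    n_frames: int
    dr: float

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame({"r_A": self.r, "g": self.g})
        with open(path, "w") as fh:
            fh.write(f"# pair={self.pair[0]}-{self.pair[1]} dr={self.dr} "
                     f"n_frames={self.n_frames}\n")
            df.to_csv(fh, sep="\t", index=False)


def compute_rdf(
    traj: Trajectory,
    sel_a: Sequence[int],
    sel_b: Sequence[int],
    dr: float = 0.02,
    r_max: float | None = None,
    pair: tuple[str, str] = ("a", "b"),
) -> RDFResult:
    """g(r) between two atom selections under minimum image.

    Normalized against the ideal-gas expectation at the bulk density of
    selection b; self-pairs (shared indices) are excluded.
    """
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    cell = traj.cell
    half_min_l = min(cell.lengths) / 2
    if r_max is None:
        r_max = half_min_l
    if r_max > half_min_l + 1e-9:
        raise ValueError(f"r_max {r_max} exceeds half the box length {half_min_l}")
    n_bins = int(np.floor(r_max / dr))
    edges = np.arange(n_bins + 1) * dr
    counts = np.zeros(n_bins)
    shared = np.intersect1d(sel_a, sel_b)
    for f in traj:
        d = min_image_displacements(
            f.coords[sel_a][:, None, :], f.coords[sel_b][None, :, :], f.cell
        )
        r = np.linalg.norm(d, axis=-1)
        if len(shared):
            for i, a in enumerate(sel_a):
                hit = np.flatnonzero(sel_b == a)
                r[i, hit] = np.inf
        counts += np.histogram(r.ravel(), bins=edges)[0]
    n_frames = len(traj)
    # shared atoms contribute no self-pair: N_a*N_b - |overlap| distinct pairs
    n_pairs = len(sel_a) * len(sel_b) - len(shared)
    centers = edges[:-1] + dr / 2
    shell = 4 * np.pi * centers**2 * dr
    norm = n_frames * shell * n_pairs / cell.volume
    g = counts / norm
    return RDFResult(r=centers, g=g, pair=pair, n_frames=n_frames, dr=dr)


def rdf_peaks(
    rdf: RDFResult,
    smooth_bins: int = 3,
    threshold: float = 1.0,
) -> list[tuple[float, float]]:
    """Local maxima of the (smoothed) g(r) above a threshold, sorted by r."""
    g = _moving_average(rdf.g, smooth_bins)
    peaks: list[tuple[float, float]] = []
    for i in range(1, len(g) - 1):
        if g[i] > threshold and g[i] >= g[i - 1] and g[i] > g[i + 1]:
            peaks.append((float(rdf.r[i]), float(g[i])))
    return peaks


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return np.asarray(y, dtype=float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(np.asarray(y, dtype=float), pad, mode="edge")
    out = np.convolve(padded, kernel, mode="valid")
    return out[: len(y)] if len(out) > len(y) else out


# ---------------------------------------------------------------------------
# coordination number
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoordinationSpec:
    """Rational switching function parameters for H counting around O."""

    r0: float = 1.32  # Angstrom
    p: int = 6
    q: int = 12

    def __post_init__(self) -> None:
        if not (self.q > self.p > 0) or self.r0 <= 0:
            raise ValueError("require q > p > 0 and r0 > 0")


def switch_terms(r: np.ndarray, spec: CoordinationSpec) -> np.ndarray:
    """[1 - (r/r0)^p] / [1 - (r/r0)^q] with the removable singularity at
    r = r0 evaluated by its limit p/q."""
    t = np.asarray(r, dtype=float) / spec.r0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (1.0 - t**spec.p) / (1.0 - t**spec.q)
    near = np.abs(t - 1.0) < 1e-8
    if np.any(near):
        out = np.where(near, spec.p / spec.q, out)
    return out


def coordination(frame: Frame, o_index: int, spec: CoordinationSpec = CoordinationSpec()) -> float:
    """Smooth hydrogen coordination number of one oxygen."""
    h_idx = frame.indices_of("H")
    if len(h_idx) == 0:
        return 0.0
    d = np.linalg.norm(
        min_image_displacements(frame.coords[o_index], frame.coords[h_idx], frame.cell),
        axis=-1,
    )
    return float(np.sum(switch_terms(d, spec)))


# ---------------------------------------------------------------------------
# 1D free-energy profiles
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergyProfile:
    centers: np.ndarray
    F: np.ndarray  # kcal/mol, nan where unsampled, min = 0
    kT: float
    counts: np.ndarray = field(default=None)

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame({"coord": self.centers, "F_kcal_mol": self.F})
        with open(path, "w") as fh:
            fh.write(f"# kT={self.kT} bin_width={self.centers[1] - self.centers[0]}\n")
            df.to_csv(fh, sep="\t", index=False)


def profile_from_samples(
    samples: np.ndarray,
    kT: float = kT_at(),
    bins: int = 100,
    value_range: tuple[float, float] = (0.0, 2.5),
) -> FreeEnergyProfile:
    """F(bin) = -kT ln p_hat(bin), min-subtracted; empty bins are nan."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("no samples")
    if kT <= 0:
        raise ValueError("kT must be > 0")
    counts, edges = np.histogram(samples, bins=bins, range=value_range)
    if np.count_nonzero(counts) == 1:
        logger.warning("all samples fall in a single bin")
    centers = (edges[:-1] + edges[1:]) / 2
    with np.errstate(divide="ignore"):
        F = -kT * np.log(counts / counts.sum())
    F[counts == 0] = np.nan
    F -= np.nanmin(F)
    return FreeEnergyProfile(centers=centers, F=F, kT=kT, counts=counts)


class NoBarrierError(ValueError):
    """Profile is monotone toward n = 0: no dissociation barrier found."""


def dissociation_delta_f(
    profile: FreeEnergyProfile,
    smooth_bins: int = 5,
    mode: str = "barrier",
    n_d: float = 0.1,
) -> float:
    """Dissociation free energy (kcal/mol) from a coordination profile.

    ``mode='barrier'``: height of the first local maximum (derivative sign
    change on the ``smooth_bins``-smoothed profile) walking from the global
    minimum toward n = 0, relative to the smoothed minimum.
    ``mode='fixed'``: smoothed F at coordination value ``n_d``.
    """
    valid = np.isfinite(profile.F)
    if valid.sum() < 3:
        raise NoBarrierError("profile too sparse")
    idx = np.flatnonzero(valid)
    F = _moving_average(profile.F[idx], smooth_bins)
    F = F - np.min(F)
    centers = profile.centers[idx]
    if mode == "fixed":
        j = int(np.argmin(np.abs(centers - n_d)))
        return float(F[j])
    imin = int(np.argmin(F))
    if imin == 0:
        raise NoBarrierError("global minimum sits at the n=0 edge; no barrier")
    i = imin
    while i > 0 and F[i - 1] >= F[i]:
        i -= 1
    if i == 0:
        raise NoBarrierError(
            "profile rises monotonically from the minimum toward n=0; "
            "no barrier found (insufficient sampling?)"
        )
    # i is the first derivative sign change (local maximum / plateau top)
    return float(F[i] - F[imin])


# ---------------------------------------------------------------------------
# 2D dihedral free-energy surface
# ---------------------------------------------------------------------------

@dataclass
class FESGrid:
    """Periodic free-energy surface over (alpha, beta) in [-pi, pi)^2."""

    edges: np.ndarray  # shared bin edges for both axes
    F: np.ndarray  # (n, n), kcal/mol, nan where unsampled, min = 0
    kT: float

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2

    def minimum_bin(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.nanargmin(self.F), self.F.shape)
        c = self.centers
        return float(c[i]), float(c[j])

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        c = self.centers
        a, b = np.meshgrid(c, c, indexing="ij")
        df = pd.DataFrame(
            {"alpha_rad": a.ravel(), "beta_rad": b.ravel(), "F_kcal_mol": self.F.ravel()}
        )
        with open(path, "w") as fh:
            fh.write(f"# kT={self.kT} bin_width={self.bin_width}\n")
            df.to_csv(fh, sep="\t", index=False)


def wrap_angle(x: np.ndarray) -> np.ndarray:
    """Wrap angles to [-pi, pi)."""
    return np.mod(np.asarray(x, dtype=float) + np.pi, 2 * np.pi) - np.pi


def fes_2d(
    alpha: np.ndarray,
    beta: np.ndarray,
    kT: float = kT_at(),
    n_bins: int = 72,
) -> FESGrid:
    """Unbiased-histogram FES over the two dihedrals, min-subtracted."""
    a = wrap_angle(alpha)
    b = wrap_angle(beta)
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    H, _, _ = np.histogram2d(a, b, bins=[edges, edges])
    with np.errstate(divide="ignore"):
        F = -kT * np.log(H / H.sum())
    F[H == 0] = np.nan
    F -= np.nanmin(F)
    return FESGrid(edges=edges, F=F, kT=kT)
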