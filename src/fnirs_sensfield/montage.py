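"""Optode montages and cortical parcellations on phantom surfaces.

Optodes are laid out as an alternating source/detector lattice snapped
onto the scalp mesh, a simplified stand-in for a full 10/5 cap; channels
are formed from neighbouring source-detector pairs whose scalp distance
falls inside the usual continuous-wave band (default 25-45 mm, i.e. the
"about 3-4 cm" separations of sparse fNIRS caps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .phantom import SurfaceMesh


@dataclass
class OptodeMontage:
    sources: np.ndarray  # (ns, 3) mm, on scalp
    detectors: np.ndarray  # (nd, 3) mm, on scalp
    channels: list[tuple[int, int]]  # (source idx, detector idx)
    channel_centers: np.ndarray  # (nc, 3) mm, scalp midpoint per channel

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_distance_mm(self, c: int) -> float:
        s, d = self.channels[c]
        return float(np.linalg.norm(self.sources[s] - self.detectors[d]))

    def optode_positions(self) -> np.ndarray:
        """All optode positions, sources first then detectors."""
        return np.vstack([self.sources, self.detectors])


@dataclass
class Parcellation:
    area_labels: np.ndarray  # one area id per pial vertex; -1 background
    area_names: dict[int, str] = field(default_factory=dict)

    @property
    def area_ids(self) -> list[int]:
        return sorted(int(a) for a in np.unique(self.area_labels) if a >= 0)

    def vertex_indices(self, area_id: int) -> np.ndarray:
        return np.flatnonzero(self.area_labels == area_id)


def place_optodes(scalp: SurfaceMesh, rows: int, cols: int, pitch_mm: float,
                  distance_band_mm: tuple[float, float] = (25.0, 45.0),
                  ) -> OptodeMontage:
    """Alternating source/detector lattice snapped to the scalp.

    The lattice is centered on the scalp patch; a site (r, c) is a source
    when (r + c) is even. Channels pair lattice-adjacent S-D neighbours;
    pairs whose realized scalp distance falls outside the band are
    excluded with a warning. Channel centers are source-detector
    midpoints re-snapped to the scalp (exact midpoints on a flat patch).
    """
    verts = scalp.vertices
    lo = verts[:, :2].min(axis=0)
    hi = verts[:, :2].max(axis=0)
    span = np.array([(cols - 1) * pitch_mm, (rows - 1) * pitch_mm])
    if np.any(span > hi - lo):
        raise ValueError("optode lattice does not fit on the scalp patch")
    origin = (lo + hi) / 2 - span / 2

    tree = cKDTree(verts)

    def snap(xy):
        _, i = tree.query([xy[0], xy[1], verts[:, 2].min()])
        # keep lateral coordinates, take scalp height at nearest vertex
        return np.array([xy[0], xy[1], verts[i, 2]])

    sources, detectors = [], []
    site_kind, site_index = {}, {}
    for r in range(rows):
        for c in range(cols):
            xy = origin + np.array([c * pitch_mm, r * pitch_mm])
            pos = snap(xy)
            if (r + c) % 2 == 0:
                site_kind[(r, c)] = "S"
                site_index[(r, c)] = len(sources)
                sources.append(pos)
            else:
                site_kind[(r, c)] = "D"
                site_index[(r, c)] = len(detectors)
                detectors.append(pos)
    sources = np.array(sources).reshape(-1, 3)
    detectors = np.array(detectors).reshape(-1, 3)

    channels, centers, excluded = [], [], 0
    for r in range(rows):
        for c in range(cols):
            for dr, dc in ((0, 1), (1, 0)):
                rr, cc = r + dr, c + dc
                if rr >= rows or cc >= cols:
                    continue
                a, b = (r, c), (rr, cc)
                if site_kind[a] == site_kind[b]:
                    continue
                if site_kind[a] == "D":
                    a, b = b, a
                s, d = site_index[a], site_index[b]
                dist = float(np.linalg.norm(sources[s] - detectors[d]))
                if not (distance_band_mm[0] <= dist <= distance_band_mm[1]):
                    excluded += 1
                    continue
                channels.append((s, d))
                centers.append(snap((sources[s][:2] + detectors[d][:2]) / 2))
    if excluded:
        warnings.warn(f"{excluded} channels excluded: source-detector distance "
                      f"outside {distance_band_mm} mm band")
    if not channels:
        raise ValueError("no channels inside the source-detector distance band")
    return OptodeMontage(sources=sources, detectors=detectors, channels=channels,
                         channel_centers=np.array(centers))


def make_parcellation(pial: SurfaceMesh,
                      boxes: list[tuple[float, float, float, float]] | None = None,
                      names: list[str] | None = None,
                      depth_split_mm: float | None = None,
                      ) -> Parcellation:
    """Partition pial vertices into synthetic cortical areas.

    ``boxes`` are lateral rectangles (xmin, xmax, ymin, ymax) in mm, one
    area per box, rejected if any two overlap on the mesh. Alternatively
    ``depth_split_mm`` splits the surface at a depth threshold into a
    gyral-crown area (0, shallower) and a sulcal-wall area (1, deeper or
    equal). Vertices in no box get the background label -1.
    """
    if pial.n_vertices == 0:
        raise ValueError("pial mesh is empty")
    v = pial.vertices
    labels = np.full(pial.n_vertices, -1, dtype=np.int64)
    area_names: dict[int, str] = {}
    if depth_split_mm is not None:
        labels[v[:, 2] < depth_split_mm] = 0
        labels[v[:, 2] >= depth_split_mm] = 1
        area_names = {0: "gyral_crown", 1: "sulcal_wall"}
    elif boxes is not None:
        claimed = np.zeros(pial.n_vertices, dtype=bool)
        for a, (x0, x1, y0, y1) in enumerate(boxes):
            inside = ((v[:, 0] >= x0) & (v[:, 0] < x1)
                      & (v[:, 1] >= y0) & (v[:, 1] < y1))
            if np.any(inside & claimed):
                raise ValueError(f"area box {a} overlaps a previous area")
            labels[inside] = a
            claimed |= inside
            name = names[a] if names else f"area_{a}"
            area_names[a] = name
    else:
        labels[:] = 0
        area_names = {0: "area_0"}
    return Parcellation(area_labels=labels, area_names=area_names)
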