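"""Synthetic fluorescence vasculature phantoms.

Normal-class images contain connected branching tube networks grown
from boundary seed points; abnormal-class images are the same networks
with a large fraction of segments deleted (fragmented, sparse vessels).
The generator aims at statistical structure (connected vs fragmented),
not photorealism: tubes, background, blur, additive noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage


@dataclass(frozen=True)
class VesselPhantomParams:
    image_size: int = 128
    n_branches: int = 5  # boundary seed points
    branch_length_range: tuple = (48.0, 96.0)
    vessel_width_range: tuple = (2.0, 5.0)
    fragmentation: float = 0.0  # probability a segment is deleted
    background_level: float = 0.08
    blur_sigma: float = 1.0
    noise_sigma: float = 0.02
    branch_prob: float = 0.35
    max_depth: int = 3

    def __post_init__(self):
        if not 0.0 <= self.fragmentation <= 1.0:
            raise ValueError("fragmentation must be in [0, 1]")
        if self.image_size < 8:
            raise ValueError("degenerate image_size")
        for lo, hi in (self.branch_length_range, self.vessel_width_range):
            if lo <= 0 or hi < lo:
                raise ValueError("ranges must be positive and ordered")


#: Class defaults: normal is connected, abnormal heavily fragmented/sparse.
NORMAL_PARAMS = VesselPhantomParams(fragmentation=0.02)
ABNORMAL_PARAMS = VesselPhantomParams(
    fragmentation=0.7, n_branches=3, branch_length_range=(24.0, 56.0),
    branch_prob=0.2, max_depth=2)


@dataclass
class VesselGraph:
    """Centerline graph: node coordinates plus (i, j, width) edges."""

    nodes: np.ndarray  # (n_nodes, 2) float image coordinates (row, col)
    edges: list  # [(node_i, node_j, width), ...]
    components: list  # list of sets of node ids, one per seed tree

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def _grow_tree(params: VesselPhantomParams, rng: np.random.Generator,
               nodes: list, edges: list, start: int, heading: float,
               width: float, depth: int):
    length = rng.uniform(*params.branch_length_range)
    step = 6.0
    n_steps = max(2, int(length / step))
    cur = start
    size = params.image_size
    center = (size / 2.0, size / 2.0)
    for _ in range(n_steps):
        # drift toward the center so trees from different seeds meet
        to_center = math.atan2(center[0] - nodes[cur][0],
                               center[1] - nodes[cur][1])
        delta = (to_center - heading + math.pi) % (2 * math.pi) - math.pi
        heading += 0.25 * delta + rng.normal(0.0, 0.22)
        r = nodes[cur][0] + step * math.sin(heading)
        c = nodes[cur][1] + step * math.cos(heading)
        r = min(max(r, 1.0), size - 2.0)
        c = min(max(c, 1.0), size - 2.0)
        nodes.append((r, c))
        nxt = len(nodes) - 1
        edges.append((cur, nxt, width))
        cur = nxt
        if depth < params.max_depth and rng.random() < params.branch_prob:
            side = 1.0 if rng.random() < 0.5 else -1.0
            _grow_tree(params, rng, nodes, edges, cur,
                       heading + side * rng.uniform(0.5, 1.1),
                       max(1.0, width * 0.75), depth + 1)
        width = max(1.0, width * 0.95)  # taper toward the tip


def generate_vessel_network(params: VesselPhantomParams,
                            rng: np.random.Generator) -> VesselGraph:
    """Seeded recursive branching from boundary seed points."""
    size = params.image_size
    nodes: list = []
    edges: list = []
    component_roots = []
    for _ in range(params.n_branches):
        side = rng.integers(4)
        t = rng.uniform(0.15, 0.85) * size
        if side == 0:
            pos, heading = (1.0, t), rng.uniform(-0.6, 0.6) + math.pi / 2
        elif side == 1:
            pos, heading = (size - 2.0, t), rng.uniform(-0.6, 0.6) - math.pi / 2
        elif side == 2:
            pos, heading = (t, 1.0), rng.uniform(-0.6, 0.6)
        else:
            pos, heading = (t, size - 2.0), rng.uniform(-0.6, 0.6) + math.pi
        nodes.append(pos)
        root = len(nodes) - 1
        component_roots.append(root)
        width = rng.uniform(*params.vessel_width_range)
        _grow_tree(params, rng, nodes, edges, root, heading, width, 0)

    # fragmentation: delete segments independently
    if params.fragmentation > 0.0:
        keep = rng.random(len(edges)) >= params.fragmentation
        edges = [e for e, k in zip(edges, keep) if k]

    # connected components over surviving edges
    parent = list(range(len(nodes)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j, _ in edges:
        parent[find(i)] = find(j)
    comps: dict = {}
    touched = {i for e in edges for i in e[:2]}
    for i in touched:
        comps.setdefault(find(i), set()).add(i)
    return VesselGraph(np.array(nodes, dtype=np.float64), edges,
                       list(comps.values()))


def _draw_segment(img: np.ndarray, p0, p1, width: float):
    """Max-combine a soft-edged thick segment into ``img``."""
    size = img.shape[0]
    rad = width / 2.0 + 1.0
    r0 = max(int(min(p0[0], p1[0]) - rad), 0)
    r1 = min(int(max(p0[0], p1[0]) + rad) + 1, size)
    c0 = max(int(min(p0[1], p1[1]) - rad), 0)
    c1 = min(int(max(p0[1], p1[1]) + rad) + 1, size)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    d = np.stack([rr - p0[0], cc - p0[1]], axis=-1).astype(np.float64)
    v = np.array([p1[0] - p0[0], p1[1] - p0[1]])
    vv = v @ v
    if vv < 1e-12:
        dist = np.hypot(d[..., 0], d[..., 1])
    else:
        t = np.clip((d @ v) / vv, 0.0, 1.0)
        proj = d - t[..., None] * v
        dist = np.hypot(proj[..., 0], proj[..., 1])
    # profile: 1 inside the tube, linear 1-px falloff at the wall
    prof = np.clip(width / 2.0 + 0.5 - dist, 0.0, 1.0)
    np.maximum(img[r0:r1, c0:c1], prof, out=img[r0:r1, c0:c1])


def render_fluorescence(graph: VesselGraph, params: VesselPhantomParams,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Rasterize tubes, add background, blur and noise; output in [0, 1]."""
    size = params.image_size
    tubes = np.zeros((size, size), dtype=np.float64)
    for i, j, width in graph.edges:
        _draw_segment(tubes, graph.nodes[i], graph.nodes[j], width)
    img = params.background_level + (0.95 - params.background_level) * tubes
    if params.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, params.blur_sigma)
    if params.noise_sigma > 0:
        rng = rng or np.random.default_rng()
        img = img + rng.normal(0.0, params.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def generate_image(params: VesselPhantomParams, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    graph = generate_vessel_network(params, rng)
    return render_fluorescence(graph, params, rng)


def generate_dataset(n_normal: int, n_abnormal: int,
                     normal_params: VesselPhantomParams = NORMAL_PARAMS,
                     abnormal_params: VesselPhantomParams = ABNORMAL_PARAMS,
                     seed: int = 0, image_size: int | None = None):
    """Labeled phantom set, shuffled with the seed.

    Returns ``(images, labels)`` with label 0 = normal, 1 = abnormal.
    """
    if n_normal < 0 or n_abnormal < 0:
        raise ValueError("counts must be >= 0")
    if image_size is not None:
        normal_params = replace(normal_params, image_size=image_size)
        abnormal_params = replace(abnormal_params, image_size=image_size)
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31, size=n_normal + n_abnormal)
    images = [generate_image(normal_params, int(s)) for s in seeds[:n_normal]]
    images += [generate_image(abnormal_params, int(s)) for s in seeds[n_normal:]]
    labels = np.array([0] * n_normal + [1] * n_abnormal)
    order = root.permutation(len(images))
    images = [images[i] for i in order]
    labels = labels[order]
    return images, labels


def write_multichannel_tiff(image: np.ndarray, path: str | Path,
                            vessel_channel: int = 0, n_channels: int = 3,
                            rng: np.random.Generator | None = None,
                            dtype=np.uint16):
    """Pack one phantom as a multichannel TIFF (channel-first).

    The vessel signal lands on ``vessel_channel``; other channels carry
    unrelated low-intensity noise so channel extraction is exercised.
    """
    if not 0 <= vessel_channel < n_channels:
        raise ValueError("vessel_channel out of range")
    rng = rng or np.random.default_rng(0)
    full = np.iinfo(dtype).max
    stack = np.empty((n_channels,) + image.shape, dtype=dtype)
    for c in range(n_channels):
        if c == vessel_channel:
            plane = image
        else:
            plane = np.clip(rng.normal(0.05, 0.02, size=image.shape), 0, 1)
        stack[c] = (plane * full + 0.5).astype(dtype)
    tifffile.imwrite(Path(path), stack, photometric="minisblack")
    return stack


def largest_component_fraction(image: np.ndarray,
                               threshold: float | None = None) -> float:
    """Fraction of vessel pixels in the largest connected component.

    Separability statistic: near 1 for connected networks, low for
    fragmented ones. Returns 0 for images with no vessel pixels.
    """
    if threshold is None:
        threshold = 0.4  # between background (~0.1) and tube peak (~0.95)
    mask = image > threshold
    if not mask.any():
        return 0.0
    labeled, n = ndimage.label(mask)
    if n == 0:
        return 0.0
    sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
    return float(sizes.max() / mask.sum())
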