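"""Stochastically-connected random field (SRF) denoising core.

A random field is placed over the pixel lattice with binary cliques inside
a square neighbourhood (default 11x11).  Unlike a standard random field,
edge existence is stochastic: the edge between sites i and j is present
with probability ``exp(-d_ij / Q)``, where ``d_ij`` is a regional (patch)
L2 distance computed from the previous layer's solution and Q is the
flexibility constant.  Present edges carry smoothness weights
``exp(-d_ij^2 / sigma^2)``, per-site normalized so the weights incident to
any site sum to at most 1.

MAP estimation decouples into a quadratic unary data-fidelity term in the
variance-stabilized (VST) domain plus the pairwise smoothness term; each
layer takes a single synchronous gradient step, and the layer's output
becomes the next layer's observation (iterative scale-space).

Internal representation
-----------------------
Unordered edges are stored per *canonical offset*: for each offset
(dy, dx) with dy > 0, or dy == 0 and dx > 0, a full-lattice array holds
the value for the edge between anchor site (y, x) and partner
(y + dy, x + dx).  Every unordered in-neighbourhood pair appears exactly
once.  This keeps sampling, weighting and the gradient fully vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = [
    "SRFConfig",
    "EdgeSet",
    "WeightMap",
    "half_offsets",
    "regional_distance",
    "distance_fields",
    "connection_probability",
    "sample_edges",
    "compute_weights",
    "deterministic_weights",
    "unary_energy",
    "pairwise_energy",
    "total_energy",
    "gradient_step",
    "denoise",
]

Site = tuple[int, int]
Offset = tuple[int, int]


@dataclass(frozen=True)
class SRFConfig:
    """All SRF algorithm knobs.

    neighborhood_size  odd side of the square neighbourhood N_i (>= 3)
    region_size        odd side of the patch R_i for regional distances
    q                  flexibility constant Q > 0 (edge-existence scale);
                       by convention defaults to the smoothness constant
    sigma              smoothness constant > 0 (weight kernel scale, in
                       VST-domain regional-distance units)
    layers             number of SRF layers l (>= 0; one gradient step each)
    lam                regularizer between likelihood and prior (>= 0)
    step               gradient step size (> 0)
    seed               master seed for stochastic clique sampling
    """

    neighborhood_size: int = 11
    region_size: int = 3
    q: float = 1.0
    sigma: float = 1.0
    layers: int = 20
    lam: float = 0.1
    step: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.neighborhood_size < 3 or self.neighborhood_size % 2 == 0:
            raise ValueError("neighborhood_size must be an odd integer >= 3")
        if self.region_size < 1 or self.region_size % 2 == 0:
            raise ValueError("region_size must be an odd integer >= 1")
        if self.neighborhood_size < self.region_size:
            raise ValueError("neighborhood_size must be >= region_size")
        if not (self.q > 0 and np.isfinite(self.q)):
            raise ValueError("flexibility constant q must be finite and > 0")
        if not (self.sigma > 0 and np.isfinite(self.sigma)):
            raise ValueError("sigma must be finite and > 0")
        if self.layers < 0:
            raise ValueError("layers must be >= 0")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not (self.step > 0):
            raise ValueError("step must be > 0")

    def to_dict(self) -> dict:
        return {
            "neighborhood": self.neighborhood_size,
            "region": self.region_size,
            "q": self.q,
            "sigma": self.sigma,
            "layers": self.layers,
            "lambda": self.lam,
            "step": self.step,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SRFConfig":
        return cls(
            neighborhood_size=int(d.get("neighborhood", 11)),
            region_size=int(d.get("region", 3)),
            q=float(d.get("q", 1.0)),
            sigma=float(d.get("sigma", 1.0)),
            layers=int(d.get("layers", 20)),
            lam=float(d.get("lambda", 0.1)),
            step=float(d.get("step", 0.5)),
            seed=d.get("seed"),
        )

    def with_seed(self, seed) -> "SRFConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# Offsets and regional distances
# ---------------------------------------------------------------------------

def half_offsets(neighborhood_size: int) -> list[Offset]:
    """Canonical offsets covering every unordered pair in the window once."""
    r = neighborhood_size // 2
    offs: list[Offset] = [(0, dx) for dx in range(1, r + 1)]
    for dy in range(1, r + 1):
        offs.extend((dy, dx) for dx in range(-r, r + 1))
    return offs


def _canonical(i: Site, j: Site) -> tuple[Site, Offset]:
    off = (j[0] - i[0], j[1] - i[1])
    if off[0] > 0 or (off[0] == 0 and off[1] > 0):
        return i, off
    if off == (0, 0):
        raise ValueError(f"self-edge at site {i}")
    return j, (-off[0], -off[1])


def _pair_slices(shape: tuple[int, int], off: Offset):
    """Aligned slices selecting anchor sites i and partners j = i + off."""
    height, width = shape
    dy, dx = off
    ys_i, ys_j = slice(0, height - dy), slice(dy, height)
    x0, x1 = max(0, -dx), width - max(0, dx)
    return (ys_i, slice(x0, x1)), (ys_j, slice(x0 + dx, x1 + dx))


def regional_distance(state, i: Site, j: Site, region_size: int) -> float:
    """Patch-normalized L2 distance between the regions around i and j.

    L2 norm of the difference of the ``region_size x region_size`` patches
    centred at the two sites (mirror padding at borders), divided by the
    patch pixel count so values are comparable across region sizes.
    """
    u = np.asarray(state, dtype=float)
    r = region_size // 2
    up = np.pad(u, r, mode="reflect")
    pi = up[i[0] : i[0] + region_size, i[1] : i[1] + region_size]
    pj = up[j[0] : j[0] + region_size, j[1] : j[1] + region_size]
    return float(np.linalg.norm(pi - pj) / (region_size * region_size))


def distance_fields(
    state, region_size: int, offsets: list[Offset]
) -> dict[Offset, np.ndarray]:
    """Regional distance to the partner at each offset, for every site.

    Returns one (H, W) array per offset; entries whose partner site falls
    outside the lattice are ``inf`` (such a pair does not exist, and both
    its connection probability and weight are identically 0).
    """
    u = np.asarray(state, dtype=float)
    height, width = u.shape
    r = region_size // 2
    patch_n = region_size * region_size
    up = np.pad(u, r, mode="reflect")
    hp, wp = up.shape
    fields: dict[Offset, np.ndarray] = {}
    for off in offsets:
        dy, dx = off
        sq = np.zeros((hp, wp))
        a0, a1 = max(0, -dy), hp - max(0, dy)
        b0, b1 = max(0, -dx), wp - max(0, dx)
        diff = up[a0:a1, b0:b1] - up[a0 + dy : a1 + dy, b0 + dx : b1 + dx]
        sq[a0:a1, b0:b1] = diff * diff
        if r:
            ssum = uniform_filter(sq, size=region_size, mode="constant") * patch_n
            ssum = ssum[r : r + height, r : r + width]
        else:
            ssum = sq
        d = np.full((height, width), np.inf)
        (ys, xs), _ = _pair_slices((height, width), off)
        d[ys, xs] = np.sqrt(np.maximum(ssum[ys, xs], 0.0)) / patch_n
        fields[off] = d
    return fields


# ---------------------------------------------------------------------------
# Stochastic cliques
# ---------------------------------------------------------------------------

def connection_probability(d, q: float):
    """Edge-existence probability ``P = exp(-d / Q)``.

    Equivalent to drawing a tolerance tau ~ Exponential(mean Q) and
    connecting iff d <= tau; monotone decreasing in d with P(0) = 1.
    """
    if not (q > 0):
        raise ValueError("flexibility constant Q must be > 0")
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("distances must be >= 0")
    p = np.exp(-d_arr / q)
    return float(p) if np.isscalar(d) else p


class EdgeSet:
    """Stochastically sampled binary cliques for one layer.

    Stores one boolean field per canonical offset: ``masks[off][y, x]``
    is True iff the edge between (y, x) and (y + off) exists.  Symmetric
    and self-edge-free by construction.
    """

    def __init__(
        self,
        shape: tuple[int, int],
        masks: dict[Offset, np.ndarray],
        distances: dict[Offset, np.ndarray] | None = None,
        region_size: int | None = None,
    ):
        self.shape = tuple(shape)
        self.masks = masks
        self.distances = distances
        self.region_size = region_size

    @property
    def offsets(self) -> list[Offset]:
        return list(self.masks)

    @property
    def n_edges(self) -> int:
        return int(sum(m.sum() for m in self.masks.values()))

    def contains(self, i: Site, j: Site) -> bool:
        anchor, off = _canonical(tuple(i), tuple(j))
        if off not in self.masks:
            return False
        y, x = anchor
        height, width = self.shape
        jy, jx = y + off[0], x + off[1]
        if not (0 <= y < height and 0 <= x < width):
            return False
        if not (0 <= jy < height and 0 <= jx < width):
            return False
        return bool(self.masks[off][y, x])

    def pairs(self) -> list[tuple[Site, Site]]:
        out = []
        for off, mask in self.masks.items():
            ys, xs = np.nonzero(mask)
            out.extend(
                (((y, x), (y + off[0], x + off[1])))
                for y, x in zip(ys.tolist(), xs.tolist())
            )
        return out

    @classmethod
    def from_pairs(
        cls, shape: tuple[int, int], pairs, region_size: int | None = None
    ) -> "EdgeSet":
        height, width = shape
        masks: dict[Offset, np.ndarray] = {}
        for i, j in pairs:
            for site in (i, j):
                if not (0 <= site[0] < height and 0 <= site[1] < width):
                    raise ValueError(f"site {site} outside {height}x{width} image")
            anchor, off = _canonical(tuple(i), tuple(j))
            if off not in masks:
                masks[off] = np.zeros(shape, dtype=bool)
            masks[off][anchor] = True
        return cls(shape, masks, region_size=region_size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EdgeSet):
            return NotImplemented
        if self.shape != other.shape:
            return False
        offs = set(self.masks) | set(other.masks)
        zero = np.zeros(self.shape, dtype=bool)
        return all(
            np.array_equal(self.masks.get(o, zero), other.masks.get(o, zero))
            for o in offs
        )


def sample_edges(state, config: SRFConfig, seed=None) -> EdgeSet:
    """Sample the stochastic clique structure from the current state.

    Each unordered in-neighbourhood pair is decided exactly once,
    independently, with probability ``exp(-d_ij / Q)``; deterministic for a
    fixed seed.  Offsets are visited in the fixed canonical order so the
    random stream is reproducible.
    """
    u = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("state must be finite")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    offsets = half_offsets(config.neighborhood_size)
    fields = distance_fields(u, config.region_size, offsets)
    masks = {}
    for off in offsets:
        p = np.exp(-fields[off] / config.q)
        masks[off] = rng.random(u.shape) < p
    return EdgeSet(u.shape, masks, distances=fields, region_size=config.region_size)


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------

class WeightMap:
    """Smoothness weights for the edges of one layer, per canonical offset."""

    def __init__(self, shape: tuple[int, int], weights: dict[Offset, np.ndarray]):
        self.shape = tuple(shape)
        self.weights = weights

    @property
    def offsets(self) -> list[Offset]:
        return list(self.weights)

    def weight(self, i: Site, j: Site) -> float:
        anchor, off = _canonical(tuple(i), tuple(j))
        if off not in self.weights:
            return 0.0
        height, width = self.shape
        jy, jx = anchor[0] + off[0], anchor[1] + off[1]
        if not (0 <= jy < height and 0 <= jx < width):
            return 0.0
        return float(self.weights[off][anchor])

    def degree(self) -> np.ndarray:
        """Sum of incident edge weights at each site."""
        deg = np.zeros(self.shape)
        for off, w in self.weights.items():
            (si, sj) = _pair_slices(self.shape, off)
            deg[si] += w[si]
            deg[sj] += w[si]
        return deg

    def items(self):
        for off, w in self.weights.items():
            ys, xs = np.nonzero(w)
            for y, x in zip(ys.tolist(), xs.tolist()):
                yield ((y, x), (y + off[0], x + off[1])), float(w[y, x])


def _site_sums(shape, weights: dict[Offset, np.ndarray]) -> np.ndarray:
    s = np.zeros(shape)
    for off, w in weights.items():
        si, sj = _pair_slices(shape, off)
        s[si] += w[si]
        s[sj] += w[si]
    return s


def _normalize(shape, raw: dict[Offset, np.ndarray]) -> dict[Offset, np.ndarray]:
    # z_ij = max(s_i, s_j, 1): symmetric, keeps weights in [0, 1] and
    # guarantees the incident weights at every site sum to <= 1.
    s = _site_sums(shape, raw)
    out = {}
    for off, w in raw.items():
        si, sj = _pair_slices(shape, off)
        z = np.maximum(np.maximum(s[si], s[sj]), 1.0)
        wn = np.zeros(shape)
        wn[si] = w[si] / z
        out[off] = wn
    return out


def compute_weights(
    state,
    edges: EdgeSet,
    sigma: float,
    region_size: int = 3,
    normalize: bool = True,
) -> WeightMap:
    """Smoothness weights ``exp(-d_ij^2 / sigma^2)`` on the sampled edges.

    Distances are the regional distances on ``state`` (reused from the
    EdgeSet when it was sampled from the same state/region size).  With
    ``normalize=True`` (default) weights are per-site normalized as in
    :func:`_normalize`; ``normalize=False`` returns the raw kernel values,
    which is what the expected-weight identity (raw weight x connection
    probability) is stated for.
    """
    if not (sigma > 0):
        raise ValueError("sigma must be > 0")
    u = np.asarray(state, dtype=float)
    if tuple(u.shape) != edges.shape:
        raise ValueError(f"state shape {u.shape} != edge lattice {edges.shape}")
    if edges.distances is not None and edges.region_size == region_size:
        fields = edges.distances
    else:
        fields = distance_fields(u, region_size, edges.offsets)
    raw = {}
    for off, mask in edges.masks.items():
        d = fields[off]
        w = np.exp(-(d * d) / (sigma * sigma))
        raw[off] = np.where(mask, w, 0.0)
    if normalize:
        return WeightMap(edges.shape, _normalize(edges.shape, raw))
    return WeightMap(edges.shape, raw)


def deterministic_weights(
    state, config: SRFConfig, mode: str = "plain", t: float | None = None
) -> WeightMap:
    """Standard-RF baseline weights on the full neighbourhood graph.

    ``plain``: ``exp(-d^2/sigma^2)`` for every in-neighbourhood pair.
    ``hard_threshold``: additionally zero where ``d > t`` (deterministic
    edge-connectivity threshold).  Raw (un-normalized) weights, for use as
    comparison baselines.
    """
    if mode not in ("plain", "hard_threshold"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "hard_threshold" and not (t is not None and t > 0):
        raise ValueError("hard_threshold mode requires a threshold T > 0")
    u = np.asarray(state, dtype=float)
    offsets = half_offsets(config.neighborhood_size)
    fields = distance_fields(u, config.region_size, offsets)
    weights = {}
    for off in offsets:
        d = fields[off]
        w = np.exp(-(d * d) / (config.sigma * config.sigma))
        if mode == "hard_threshold":
            w = np.where(d > t, 0.0, w)
        weights[off] = w
    return WeightMap(u.shape, weights)


# ---------------------------------------------------------------------------
# Energies and the optimizer
# ---------------------------------------------------------------------------

def unary_energy(state, observation_vst) -> float:
    """Quadratic VST-domain data fidelity ``sum_i (t_i - t_obs,i)^2``."""
    t = np.asarray(state, dtype=float)
    tobs = np.asarray(observation_vst, dtype=float)
    if t.shape != tobs.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {tobs.shape}")
    return float(np.sum((t - tobs) ** 2))


def pairwise_energy(state, weights: WeightMap) -> float:
    """Smoothness energy ``sum_{(i,j) in edges} w_ij (u_i - u_j)^2``."""
    u = np.asarray(state, dtype=float)
    if tuple(u.shape) != weights.shape:
        raise ValueError(f"state shape {u.shape} != weight lattice {weights.shape}")
    total = 0.0
    for off, w in weights.weights.items():
        si, sj = _pair_slices(weights.shape, off)
        diff = u[si] - u[sj]
        total += float(np.sum(w[si] * diff * diff))
    return total


def total_energy(state, observation_vst, weights: WeightMap, lam: float) -> float:
    """MAP energy: unary data fidelity plus ``lam`` times the prior."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    return unary_energy(state, observation_vst) + lam * pairwise_energy(state, weights)


def gradient_step(
    state, observation_vst, weights: WeightMap, lam: float, step: float
) -> np.ndarray:
    """One synchronous gradient step on :func:`total_energy`.

    ``grad_i = 2 (t_i - t_obs,i) + lam * sum_j 2 w_ij (t_i - t_j)`` with the
    weights held fixed; all sites update simultaneously (Jacobi-style), so
    the result is independent of any site ordering.
    """
    if not (step > 0):
        raise ValueError("step must be > 0")
    t = np.asarray(state, dtype=float)
    tobs = np.asarray(observation_vst, dtype=float)
    if t.shape != tobs.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {tobs.shape}")
    grad = 2.0 * (t - tobs)
    for off, w in weights.weights.items():
        si, sj = _pair_slices(weights.shape, off)
        contrib = 2.0 * w[si] * (t[si] - t[sj])
        grad[si] += lam * contrib
        grad[sj] -= lam * contrib
    return t - step * grad


def denoise(
    observation,
    params,
    config: SRFConfig,
    energy_log: list | None = None,
) -> np.ndarray:
    """Multi-layer SRF denoising of one Poisson-Gaussian observation.

    The observation is variance-stabilized, then each layer (i) samples
    stochastic cliques from the previous solution, (ii) computes normalized
    smoothness weights from it, and (iii) takes a single gradient step on
    the layer energy, with the previous solution serving as the layer's
    observation (iterative scale-space).  The final state is mapped back
    through the inverse VST.  Deterministic given ``config.seed``;
    ``layers=0`` reduces to the VST round trip.

    If ``energy_log`` is a list, one ``(before, after)`` total-energy pair
    per layer is appended.
    """
    from .noise_model import vst_forward, vst_inverse

    v = np.asarray(observation, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("observation must be finite")
    t = vst_forward(v, params)
    if config.layers > 0:
        children = np.random.SeedSequence(config.seed).spawn(config.layers)
        for child in children:
            edges = sample_edges(t, config, seed=child)
            weights = compute_weights(
                t, edges, config.sigma, config.region_size
            )
            obs_layer = t  # previous solution is this layer's observation
            if energy_log is not None:
                e0 = total_energy(t, obs_layer, weights, config.lam)
            t = gradient_step(t, obs_layer, weights, config.lam, config.step)
            if energy_log is not None:
                energy_log.append(
                    (e0, total_energy(t, obs_layer, weights, config.lam))
                )
    return vst_inverse(t, params)
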