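"""Handcrafted sequence descriptors.

Three descriptors turn one amino-acid sequence into fixed-length numeric
vectors:

* **LD** (local descriptor, 630-dim): the sequence is cut into ten
  overlapping regions (seven spanning 25% of the length, three spanning
  75%); each region is summarized by composition / transition /
  distribution statistics over a 7-group physicochemical alphabet
  (7 + 21 + 35 = 63 values per region).
* **F-vector** (140-dim): for each of the 35 ways of collapsing the 7
  groups into classes of sizes 4/1/1/1, residues are placed on the unit
  circle (each class owns a quarter arc, residues advance along it in
  occurrence order) and the point cloud is summarized by the mean and
  sample variance of each coordinate.
* **APAAC / APAACplus** (20+2λ / 20+4λ): amphiphilic pseudo-amino-acid
  composition — residue frequencies plus lagged hydrophobicity and
  hydrophilicity correlation terms; the "plus" variant adds tripeptide
  (triple-product) correlation terms at the same lags.

Descriptors are defined on the 20 standard residues only; non-standard
letters are stripped before encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .io import STANDARD_RESIDUES

LD_DIM = 630
FVECTOR_DIM = 140
N_GROUPS = 7
N_PARTITIONS = 35

#: Default 7-group physicochemical alphabet (dipole/volume grouping).
DEFAULT_GROUPS: dict[str, int] = {
    **{aa: 1 for aa in "AGV"},
    **{aa: 2 for aa in "ILFP"},
    **{aa: 3 for aa in "YMTS"},
    **{aa: 4 for aa in "HNQW"},
    **{aa: 5 for aa in "RK"},
    **{aa: 6 for aa in "DE"},
    **{aa: 7 for aa in "C"},
}


@dataclass(frozen=True)
class GroupAlphabet:
    """Mapping from the 20 standard residues to group indices 1..7."""

    mapping: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUPS))

    def __post_init__(self) -> None:
        missing = set(STANDARD_RESIDUES) - set(self.mapping)
        if missing:
            raise ValueError(f"group alphabet misses residues {sorted(missing)}")
        groups = set(self.mapping.values())
        if groups != set(range(1, N_GROUPS + 1)):
            raise ValueError(
                f"group alphabet must use exactly groups 1..7, got {sorted(groups)}"
            )

    def encode(self, sequence: str) -> np.ndarray:
        """Group index (1..7) per residue; non-standard residues dropped."""
        return np.array(
            [self.mapping[aa] for aa in sequence if aa in self.mapping], dtype=np.int64
        )


def _default_regions() -> tuple[tuple[float, float], ...]:
    quarter = [(s / 8, s / 8 + 0.25) for s in range(0, 7)]
    threequarter = [(s / 8, s / 8 + 0.75) for s in range(0, 3)]
    return tuple(quarter + threequarter)


@dataclass(frozen=True)
class RegionScheme:
    """Ten (start_fraction, end_fraction) windows: seven 25%-long, three 75%-long."""

    regions: tuple[tuple[float, float], ...] = field(default_factory=_default_regions)

    def __post_init__(self) -> None:
        if len(self.regions) != 10:
            raise ValueError(f"region scheme needs exactly 10 regions, got {len(self.regions)}")
        spans = sorted(round(e - s, 9) for s, e in self.regions)
        if spans[:7] != [0.25] * 7 or spans[7:] != [0.75] * 3:
            raise ValueError("region scheme must have seven 25% and three 75% windows")


@dataclass(frozen=True)
class ApaacConfig:
    """Pseudo-amino-acid composition settings: max lag λ and weights w1 (pair
    terms) / w2 (triplet terms)."""

    lam: int = 30
    w1: float = 0.5
    w2: float = 0.5

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise ValueError(f"lambda must be >= 1, got {self.lam}")
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("weights w1, w2 must be non-negative")


class PropertyTable:
    """Standardized hydrophobicity (h1) and hydrophilicity (h2) per residue.

    Values are z-scored over the 20 standard residues (zero mean, unit
    population standard deviation), as pseudo-amino-acid composition
    requires.
    """

    def __init__(self, hydrophobicity: Mapping[str, float], hydrophilicity: Mapping[str, float]):
        for table, name in ((hydrophobicity, "hydrophobicity"), (hydrophilicity, "hydrophilicity")):
            if set(table) != set(STANDARD_RESIDUES):
                raise ValueError(f"{name} table must cover exactly the 20 standard residues")

        def standardize(table: Mapping[str, float]) -> np.ndarray:
            v = np.array([table[aa] for aa in STANDARD_RESIDUES], dtype=float)
            return (v - v.mean()) / v.std()

        self.h1 = standardize(hydrophobicity)
        self.h2 = standardize(hydrophilicity)
        self._index = {aa: i for i, aa in enumerate(STANDARD_RESIDUES)}

    @classmethod
    def default(cls) -> "PropertyTable":
        """Load the packaged hydropathy tables."""
        text = resources.files("dfppi").joinpath("data/apaac_properties.tsv").read_text()
        h1: dict[str, float] = {}
        h2: dict[str, float] = {}
        for line in text.strip().splitlines()[1:]:
            aa, a, b = line.split("\t")
            h1[aa] = float(a)
            h2[aa] = float(b)
        return cls(h1, h2)

    def encode(self, sequence: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-residue (h1, h2) arrays; non-standard residues dropped."""
        idx = np.array([self._index[aa] for aa in sequence if aa in self._index], dtype=np.int64)
        return self.h1[idx], self.h2[idx]


@dataclass(frozen=True)
class FeatureVector:
    """A named fixed-dimension numeric encoding of one sequence."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.name}: non-finite feature values")

    @property
    def dim(self) -> int:
        return self.values.size


# ---------------------------------------------------------------------------
# Local descriptor (composition / transition / distribution over 10 regions)
# ---------------------------------------------------------------------------

MIN_LD_LENGTH = 8  # shortest length for which every default region is non-empty

#: The 21 unordered distinct group pairs, lexicographic.
TRANSITION_PAIRS: tuple[tuple[int, int], ...] = tuple(combinations(range(1, 8), 2))


def split_regions(sequence: str, scheme: RegionScheme | None = None) -> list[str]:
    """Cut a sequence into the scheme's ten fragments.

    A window (s, e) selects 1-based residues floor(s*L)+1 .. floor(e*L).
    """
    scheme = scheme or RegionScheme()
    L = len(sequence)
    if L < MIN_LD_LENGTH:
        raise ValueError(
            f"sequence of length {L} too short for region splitting "
            f"(minimum {MIN_LD_LENGTH})"
        )
    out = []
    for s, e in scheme.regions:
        lo = int(np.floor(s * L))          # 0-based start
        hi = int(np.floor(e * L))          # 0-based exclusive end
        out.append(sequence[lo:hi])
    return out


def ctd_region_vector(region: str, groups: GroupAlphabet | None = None) -> np.ndarray:
    """63-dim composition/transition/distribution vector of one region.

    Composition: 7 group frequencies.  Transition: for each of the 21
    unordered group pairs, the fraction of adjacent residue pairs whose
    groups alternate between the two.  Distribution: for each group, the
    length-normalized 1-based positions of its first, 25th-percentile,
    median, 75th-percentile and last occurrence (zeros when absent).
    """
    groups = groups or GroupAlphabet()
    g = groups.encode(region)
    L = g.size
    if L == 0:
        raise ValueError("empty region (or region of only non-standard residues)")

    comp = np.bincount(g, minlength=8)[1:8] / L

    trans = np.zeros(21)
    if L > 1:
        a, b = g[:-1], g[1:]
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        diff = lo != hi
        for t, (i, j) in enumerate(TRANSITION_PAIRS):
            trans[t] = np.count_nonzero(diff & (lo == i) & (hi == j))
        trans /= L - 1

    dist = np.zeros((7, 5))
    for gi in range(1, 8):
        pos = np.flatnonzero(g == gi) + 1  # 1-based positions
        n = pos.size
        if n == 0:
            continue
        picks = [
            pos[0],
            pos[max(1, int(np.ceil(0.25 * n))) - 1],
            pos[max(1, int(np.ceil(0.50 * n))) - 1],
            pos[max(1, int(np.ceil(0.75 * n))) - 1],
            pos[-1],
        ]
        dist[gi - 1] = np.array(picks) / L

    return np.concatenate([comp, trans, dist.ravel()])


def ld_vector(
    sequence: str,
    groups: GroupAlphabet | None = None,
    scheme: RegionScheme | None = None,
) -> FeatureVector:
    """630-dim local descriptor: the ten regions' C/T/D vectors, region-major."""
    groups = groups or GroupAlphabet()
    stripped = "".join(aa for aa in sequence if aa in groups.mapping)
    parts = [ctd_region_vector(r, groups) for r in split_regions(stripped, scheme)]
    return FeatureVector("ld", np.concatenate(parts))


# ---------------------------------------------------------------------------
# F-vector (unit-circle trace over the 35 group partitions)
# ---------------------------------------------------------------------------


def enumerate_partitions() -> list[dict[int, int]]:
    """The 35 assignments of groups 1..7 to classes G0..G3 (sizes 4/1/1/1).

    G0 combinations are enumerated lexicographically; the three leftover
    groups fill G1, G2, G3 in ascending group order.
    """
    out = []
    for quad in combinations(range(1, 8), 4):
        rest = sorted(set(range(1, 8)) - set(quad))
        assign = {g: 0 for g in quad}
        assign.update({g: k + 1 for k, g in enumerate(rest)})
        out.append(assign)
    return out


_PARTITIONS = enumerate_partitions()
# 35 x 7 table: class of group (g) under partition p = _CLS_TABLE[p, g-1]
_CLS_TABLE = np.array([[p[g] for g in range(1, 8)] for p in _PARTITIONS], dtype=np.int64)


def circle_trace(
    sequence: str,
    assignment: Mapping[int, int],
    groups: GroupAlphabet | None = None,
) -> np.ndarray:
    """Place residues on the unit circle under one 4-class assignment.

    A residue of class Gk is the point at angle (n_j(Gk)/(n(Gk)+1) + k)·π/2,
    where n_j(Gk) counts class-k residues among the first j and n(Gk) is the
    class total — residues sweep their class's quarter arc in order.
    Returns an (L, 2) array of (x, y) points.
    """
    groups = groups or GroupAlphabet()
    g = groups.encode(sequence)
    cls = np.array([assignment[int(gi)] for gi in g], dtype=np.int64)
    theta = np.empty(g.size)
    for k in range(4):
        mask = cls == k
        n_k = np.count_nonzero(mask)
        if n_k == 0:
            continue
        ranks = np.arange(1, n_k + 1)
        theta[mask] = (ranks / (n_k + 1) + k) * (np.pi / 2)
    return np.column_stack([np.cos(theta), np.sin(theta)])


def fvector(sequence: str, groups: GroupAlphabet | None = None) -> FeatureVector:
    """140-dim F-vector: (mean_x, var_x, mean_y, var_y) per partition.

    Variances are sample variances (denominator L−1); both are defined as 0
    for single-residue sequences.
    """
    groups = groups or GroupAlphabet()
    g = groups.encode(sequence)
    L = g.size
    if L == 0:
        raise ValueError("sequence contains no standard residues")

    values = np.empty((N_PARTITIONS, 4))
    for p in range(N_PARTITIONS):
        cls = _CLS_TABLE[p, g - 1]
        theta = np.empty(L)
        for k in range(4):
            mask = cls == k
            n_k = np.count_nonzero(mask)
            if n_k == 0:
                continue
            theta[mask] = (np.arange(1, n_k + 1) / (n_k + 1) + k) * (np.pi / 2)
        x = np.cos(theta)
        y = np.sin(theta)
        f1 = x.mean()
        f3 = y.mean()
        if L > 1:
            f2 = np.square(x - f1).sum() / (L - 1)
            f4 = np.square(y - f3).sum() / (L - 1)
        else:
            f2 = f4 = 0.0
        values[p] = (f1, f2, f3, f4)
    return FeatureVector("fvector", values.ravel())


# ---------------------------------------------------------------------------
# APAAC / APAACplus
# ---------------------------------------------------------------------------


def _apaac_terms(
    sequence: str, cfg: ApaacConfig, props: PropertyTable
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frequencies f (20), pair terms tau (2λ) and triplet terms upsilon (2λ).

    tau_{2k-1} (hydrophobicity) and tau_{2k} (hydrophilicity) average the
    lag-k products h_i·h_{i+k}; upsilon terms average the triple products
    h_i·h_{i+k}·h_{i+2k}.  Terms whose averaging window is empty (L−k ≤ 0 or
    L−2k ≤ 0) are zero, so short sequences remain encodable.
    """
    seq = "".join(aa for aa in sequence if aa in props._index)
    L = len(seq)
    if L == 0:
        raise ValueError("sequence contains no standard residues")
    idx = np.array([props._index[aa] for aa in seq], dtype=np.int64)
    freqs = np.bincount(idx, minlength=20) / L

    h1, h2 = props.h1[idx], props.h2[idx]
    tau = np.zeros(2 * cfg.lam)
    ups = np.zeros(2 * cfg.lam)
    for k in range(1, cfg.lam + 1):
        if L - k > 0:
            tau[2 * k - 2] = (h1[:-k] * h1[k:]).sum() / (L - k)
            tau[2 * k - 1] = (h2[:-k] * h2[k:]).sum() / (L - k)
        if L - 2 * k > 0:
            m = L - 2 * k
            ups[2 * k - 2] = (h1[:m] * h1[k : k + m] * h1[2 * k :]).sum() / m
            ups[2 * k - 1] = (h2[:m] * h2[k : k + m] * h2[2 * k :]).sum() / m
    return freqs, tau, ups


def apaac_vector(
    sequence: str,
    cfg: ApaacConfig | None = None,
    props: PropertyTable | None = None,
) -> FeatureVector:
    """(20+2λ)-dim amphiphilic pseudo-amino-acid composition."""
    cfg = cfg or ApaacConfig()
    props = props or PropertyTable.default()
    freqs, tau, _ = _apaac_terms(sequence, cfg, props)
    denom = freqs.sum() + cfg.w1 * tau.sum()
    return FeatureVector("apaac", np.concatenate([freqs, cfg.w1 * tau]) / denom)


def apaacplus_vector(
    sequence: str,
    cfg: ApaacConfig | None = None,
    props: PropertyTable | None = None,
) -> FeatureVector:
    """(20+4λ)-dim APAACplus: APAAC extended with tripeptide correlation terms."""
    cfg = cfg or ApaacConfig()
    props = props or PropertyTable.default()
    freqs, tau, ups = _apaac_terms(sequence, cfg, props)
    denom = freqs.sum() + cfg.w1 * tau.sum() + cfg.w2 * ups.sum()
    return FeatureVector(
        "apaacplus", np.concatenate([freqs, cfg.w1 * tau, cfg.w2 * ups]) / denom
    )


def handcrafted_vector(
    sequence: str,
    groups: GroupAlphabet | None = None,
    scheme: RegionScheme | None = None,
    cfg: ApaacConfig | None = None,
    props: PropertyTable | None = None,
) -> FeatureVector:
    """LD ∥ F-vector ∥ APAACplus concatenation (910-dim at λ=30)."""
    groups = groups or GroupAlphabet()
    parts = [
        ld_vector(sequence, groups, scheme).values,
        fvector(sequence, groups).values,
        apaacplus_vector(sequence, cfg, props).values,
    ]
    return FeatureVector("handcrafted", np.concatenate(parts))


HANDCRAFTED_DIM = LD_DIM + FVECTOR_DIM + 20 + 4 * ApaacConfig().lam
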