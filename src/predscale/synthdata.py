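"""Seeded generators for inputs with the pipeline's assumed structure.

The study's real inputs (a pruned carnivoran phylogeny with predator and
maximum-prey masses, a fossil-census table, thin-section clast
measurements) are not publicly archived, so this module emulates their
statistical structure: a unit-depth pure-birth tree, traits with a linear
predator-to-max-prey relation and phylogenetically correlated residuals, a
skeletal census of 1522 individuals dominated (~90%) by a single small
ornithischian, and clast populations with class-specific lognormal sizes
and Beta-shaped roundness/sphericity.  Every generator is a pure function
of its arguments and seed: identical inputs give byte-identical output.

Defaults mirror the study conditions: 64 solitary + 12 pack species with
body masses spanning 0.1-500 kg, a prey-mass slope near 1 with Pagel's
lambda near 0.7, and a residual scale of 0.5 log10 units (an R^2 around
0.8 over that mass range, typical of carnivoran maximum-prey regressions).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .clasts import ClastRecord
from .community import ns_ratio
from .phylocomp import CovarianceModel, Phylogeny, model_covariance, read_newick

__all__ = [
    "CarnivoranConfig",
    "ClastSimConfig",
    "default_carnivoran_config",
    "simulate_tree",
    "simulate_traits",
    "simulate_census",
    "simulate_clasts",
    "lujiatun_like_census",
]


@dataclasses.dataclass(frozen=True)
class CarnivoranConfig:
    """Conditions for the carnivoran-like predator/max-prey simulation."""

    n_solitary: int = 64
    n_pack: int = 12
    mass_range_kg: tuple[float, float] = (0.1, 500.0)
    slope: float = 1.0
    intercept: float = 0.3
    model_kind: str = "LAMBDA"
    theta: float = 0.7
    residual_scale: float = 0.5

    @property
    def n_taxa(self) -> int:
        return self.n_solitary + self.n_pack


def default_carnivoran_config() -> CarnivoranConfig:
    return CarnivoranConfig()


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


class _Node:
    __slots__ = ("birth", "split", "children", "label")

    def __init__(self, birth: float):
        self.birth = birth
        self.split: float | None = None
        self.children: list["_Node"] = []
        self.label: str | None = None


def simulate_tree(n_taxa: int, seed: int) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree rescaled to unit depth.

    Starting from two lineages, after an Exp(k)-distributed wait a uniformly
    chosen lineage bifurcates, until ``n_taxa`` lineages exist; a final
    stretch beyond the last split sets the depth, and all times are divided
    by it.  Tips are labelled sp001.. in preorder, so the Newick string is
    reproducible per seed.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    root = _Node(0.0)
    root.split = 0.0
    a, b = _Node(0.0), _Node(0.0)
    root.children = [a, b]
    active = [a, b]
    t = 0.0
    for k in range(2, n_taxa):
        t += rng.exponential(1.0 / k)
        node = active.pop(int(rng.integers(len(active))))
        node.split = t
        node.children = [_Node(t), _Node(t)]
        active.extend(node.children)
    depth = t + rng.exponential(1.0 / n_taxa) + 0.05

    counter = [0]
    width = max(3, len(str(n_taxa)))

    def newick(node: _Node) -> str:
        end = node.split if node.children else depth
        length = (end - node.birth) / depth
        if not node.children:
            counter[0] += 1
            return f"sp{counter[0]:0{width}d}:{length:.12f}"
        inner = ",".join(newick(ch) for ch in node.children)
        return f"({inner}):{length:.12f}"

    return read_newick(newick(root) + ";")


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------


def simulate_traits(
    tree: Phylogeny,
    config: CarnivoranConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Predator and maximum-prey masses on a tree, with correlated residuals.

    log10 predator mass x is log-uniform over the configured range;
    log10 max prey mass y = intercept + slope*x + eps with eps multivariate
    normal under the configured trait-evolution covariance (unit-diagonal
    scale residual_scale**2 on a unit-depth tree).  Hunting modes are
    assigned by a seeded permutation so stratum sizes match the config.

    Returns the external trait-table layout
    ``species, mass_kg, max_prey_kg, mode``.
    """
    config = config or default_carnivoran_config()
    n = tree.n_tips
    rng = np.random.default_rng(seed)
    lo, hi = np.log10(config.mass_range_kg[0]), np.log10(config.mass_range_kg[1])
    x = rng.uniform(lo, hi, size=n)
    C = tree.shared_time_matrix()
    V = model_covariance(C, CovarianceModel(config.model_kind, config.theta))
    L = np.linalg.cholesky(V + 1e-12 * np.eye(n))
    eps = config.residual_scale * (L @ rng.standard_normal(n))
    y = config.intercept + config.slope * x + eps
    # stratum sizes scale with the tree when it differs from the config
    n_sol = int(round(n * config.n_solitary / config.n_taxa))
    modes = np.array(["solitary"] * n_sol + ["pack"] * (n - n_sol))
    rng.shuffle(modes)
    return pd.DataFrame(
        {
            "species": list(tree.tip_labels),
            "mass_kg": 10.0**x,
            "max_prey_kg": 10.0**y,
            "mode": modes,
        }
    )


# ---------------------------------------------------------------------------
# Census
# ---------------------------------------------------------------------------


def simulate_census(
    true_abundances,
    masses_kg,
    total_skeletons: int,
    seed: int = 0,
    species=None,
    trophic_levels=None,
) -> pd.DataFrame:
    """Preservation-biased skeletal census from true living abundances.

    The expected skeleton share of species i is proportional to
    true_share_i / (N/S ratio at its mass) -- small-bodied species leave
    proportionally fewer observable skeletons -- and counts are drawn
    multinomially.
    """
    a = np.asarray(true_abundances, dtype=float)
    W = np.asarray(masses_kg, dtype=float)
    if len(a) != len(W):
        raise ValueError("abundances and masses must align")
    if np.any(a < 0) or not np.isclose(a.sum(), 1.0):
        raise ValueError("true abundances must be nonnegative and sum to 1")
    if np.any(W <= 0):
        raise ValueError("masses must be positive")
    if total_skeletons <= 0:
        raise ValueError("total_skeletons must be positive")
    p = a / ns_ratio(W)
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(int(total_skeletons), p)
    k = len(a)
    if species is None:
        species = [f"taxon{i + 1:02d}" for i in range(k)]
    if trophic_levels is None:
        trophic_levels = ["primary consumer"] * k
    return pd.DataFrame(
        {
            "species": list(species),
            "count": counts,
            "mass_kg": W,
            "trophic_level": list(trophic_levels),
        }
    )


def lujiatun_like_census() -> pd.DataFrame:
    """A fixed synthetic census emulating the Lujiatun skeletal tally.

    Entirely synthetic species and numbers (not the study's table, which is
    not publicly archived): 1522 individuals, one small ornithischian at
    90.0% raw abundance, per-capita masses spanning 0.01-1000 kg, a
    large-bodied sauropod known only from teeth, and both trophic levels
    represented.
    """
    rows = [
        # species, count, mass_kg, trophic_level, teeth_only
        ("psittacosaurid A", 1370, 10.6, "primary consumer", False),
        ("sauropod B (teeth only)", 3, 1000.0, "primary consumer", True),
        ("ornithopod C", 45, 150.0, "primary consumer", False),
        ("maniraptoran D", 30, 2.5, "secondary consumer", False),
        ("tyrannosauroid E", 8, 50.0, "secondary consumer", False),
        ("carnosaur F", 2, 300.0, "secondary consumer", False),
        ("mammal G", 24, 3.4, "secondary consumer", False),
        ("mammal H", 15, 0.25, "secondary consumer", False),
        ("lizard I", 10, 0.05, "secondary consumer", False),
        ("amphibian J", 10, 0.01, "secondary consumer", False),
        ("bird K", 5, 0.3, "secondary consumer", False),
    ]
    df = pd.DataFrame(rows, columns=["species", "count", "mass_kg", "trophic_level", "teeth_only"])
    assert df["count"].sum() == 1522
    return df


# ---------------------------------------------------------------------------
# Clasts
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ClastSimConfig:
    """Distribution parameters for synthetic clast populations.

    Size means default to the thin-section characterization (lithic mean
    0.46 mm, mineral mean 0.11 mm) with the lithic fraction of the sized
    subset (165/373).
    """

    lithic_fraction: float = 165.0 / 373.0
    lithic_size_logmean: float = float(np.log(0.46) - 0.5)  # lognormal mean 0.46
    lithic_size_logsd: float = 1.0
    mineral_size_logmean: float = float(np.log(0.11) - 0.18)  # lognormal mean 0.11
    mineral_size_logsd: float = 0.6
    sphericity_beta: tuple[float, float] = (5.0, 2.0)
    roundness_beta: tuple[float, float] = (2.0, 3.0)  # angular assemblage
    corner_count_range: tuple[int, int] = (3, 8)

    def size_lognormal(self, cls: str) -> tuple[float, float]:
        if cls == "lithic":
            return self.lithic_size_logmean, self.lithic_size_logsd
        return self.mineral_size_logmean, self.mineral_size_logsd


def simulate_clasts(
    n: int, params: ClastSimConfig | None = None, seed: int = 0
) -> list[ClastRecord]:
    """Draw ``n`` ClastRecords satisfying all record invariants.

    Sizes are class-specific lognormals; sphericity and roundness are Beta
    draws, with corner radii jittered around the target roundness so their
    mean reproduces it exactly.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    params = params or ClastSimConfig()
    if not 0 <= params.lithic_fraction <= 1:
        raise ValueError("lithic fraction must lie in [0, 1]")
    for pair in (params.sphericity_beta, params.roundness_beta):
        if min(pair) <= 0:
            raise ValueError("Beta parameters must be positive")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        cls = "lithic" if rng.random() < params.lithic_fraction else "mineral"
        mu, sd = params.size_lognormal(cls)
        size = float(rng.lognormal(mu, sd))
        psi = float(rng.beta(*params.sphericity_beta))
        psi = min(max(psi, 1e-3), 1.0)
        d_max = 2.0 * size / (1.0 + psi)
        d_min = psi * d_max
        r_max = d_min / 2.0  # inscribed circle cannot exceed the short axis
        R = float(rng.beta(*params.roundness_beta))
        R = min(max(R, 1e-3), 1.0)
        k = int(rng.integers(params.corner_count_range[0], params.corner_count_range[1] + 1))
        jitter = rng.uniform(-1.0, 1.0, size=k) * 0.4 * min(R, 1.0 - R)
        u = R + (jitter - jitter.mean())  # mean exactly R, each in (0, 1]
        records.append(
            ClastRecord(
                id=f"clast{i + 1:04d}",
                clast_class=cls,
                corner_radii=tuple(float(v) * r_max for v in u),
                r_max=r_max,
                d_min=d_min,
                d_max=d_max,
                colour=["grey", "brown", "black", "red"][int(rng.integers(4))],
                composition=(
                    ["igneous", "unknown", "sedimentary"][int(rng.integers(3))]
                    if cls == "lithic"
                    else ["feldspar", "quartz", "fe/ti-oxide", "biotite"][int(rng.integers(4))]
                ),
            )
        )
    return records
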