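"""Population-size estimators.

Two estimators operate on the reconstructed pedigree and the raw sample
stream:

* the pedigree-based (Creel-Rosenblatt) estimator
  N_hat = N_s + N_in + N_un, where N_s is the count of sampled genotypes,
  N_in the mortality-corrected number of parents inferred as missing from
  parent-offspring dyads (with a full-sibling screen and a dam:sire-ratio
  scaling so a polygynandrous parent is not inferred once per offspring),
  and N_un an estimate of individuals that neither bred nor were sampled;

* the rarefaction (accumulation-curve) estimator: the cumulative count of
  unique genotypes y against samples drawn x is fitted with the saturation
  model y = a x / (b + x), whose asymptote a estimates population size; the
  fit is repeated over random sample orderings and the asymptotes averaged.

Bounds for the pedigree estimator follow the original prescription: the
lower bound is the genotype count itself; the upper bound treats every dyad
as one new individual with zero mortality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import least_squares

from .parentage import PedigreeResult
from .relatedness import RelatednessMatrix

#: annual mortality applied to inferred dams / sires (breeding-age adults)
DAM_MORTALITY = 0.072
SIRE_MORTALITY = 0.116

FS_THRESHOLD = 0.375  # midpoint of the half-sib (0.25) and full-sib (0.5) expectations

STRATEGIES = ("nonbreeder_fraction", "breeder_ratio", "none")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class CreInputs:
    """Inputs to the pedigree-based estimator."""

    n_s: int
    b_s: int
    dyads: list[tuple[str, str, str]]  # (offspring, known_parent, parent_sex)
    rho: float  # dam:sire ratio in the reconstructed pedigree
    m_f: float = DAM_MORTALITY
    m_m: float = SIRE_MORTALITY
    relatedness: RelatednessMatrix | None = None
    fs_threshold: float = FS_THRESHOLD

    def __post_init__(self) -> None:
        if self.b_s > self.n_s:
            raise ValueError("B_s cannot exceed N_s")
        if not (self.rho > 0):
            raise ValueError("dam:sire ratio must be positive")
        if not (0 <= self.m_f <= 1 and 0 <= self.m_m <= 1):
            raise ValueError("mortalities must be in [0, 1]")

    @classmethod
    def from_pedigree(
        cls,
        pedigree: PedigreeResult,
        relatedness: RelatednessMatrix | None = None,
        m_f: float = DAM_MORTALITY,
        m_m: float = SIRE_MORTALITY,
        fs_threshold: float = FS_THRESHOLD,
    ) -> "CreInputs":
        # an uninformative pedigree (no sires or no dams) carries no ratio
        # information; fall back to parity
        if pedigree.distinct_sires > 0 and pedigree.distinct_dams > 0:
            rho = pedigree.distinct_dams / pedigree.distinct_sires
        else:
            rho = 1.0
        return cls(
            n_s=pedigree.n_s,
            b_s=pedigree.b_s,
            dyads=pedigree.dyads,
            rho=rho,
            m_f=m_f,
            m_m=m_m,
            relatedness=relatedness,
            fs_threshold=fs_threshold,
        )


def screen_fullsib_dyads(
    dyads: Sequence[tuple[str, str, str]],
    relatedness: RelatednessMatrix | None,
    fs_threshold: float = FS_THRESHOLD,
):
    """Collapse full-sibling dyad groups onto a single missing parent.

    Offspring sharing the same known parent whose pairwise Lynch-Ritland r
    reaches ``fs_threshold`` are taken to be full siblings; each connected
    component of two or more such offspring contributes exactly one inferred
    missing parent (of the sex opposite the known parent), and its dyads are
    removed from the remainder handed to the ratio method.

    Returns (fs_components, inferred_sires, inferred_dams, remaining_dyads).
    """
    dyads = list(dyads)
    if relatedness is None:
        return [], 0, 0, dyads
    by_parent: dict[tuple[str, str], list[tuple[str, str, str]]] = {}
    for off, par, psex in dyads:
        by_parent.setdefault((par, psex), []).append((off, par, psex))
    inferred_sires = 0
    inferred_dams = 0
    components: list[list[str]] = []
    consumed: set[tuple[str, str]] = set()
    for (par, psex), group in sorted(by_parent.items()):
        if len(group) < 2:
            continue
        g = nx.Graph()
        offspring = [off for off, _, _ in group]
        g.add_nodes_from(offspring)
        for i in range(len(offspring)):
            for j in range(i + 1, len(offspring)):
                r = relatedness.pair(offspring[i], offspring[j])
                if np.isfinite(r) and r >= fs_threshold:
                    g.add_edge(offspring[i], offspring[j])
        for comp in nx.connected_components(g):
            if len(comp) >= 2:
                components.append(sorted(comp))
                if psex == "F":
                    inferred_sires += 1
                else:
                    inferred_dams += 1
                consumed |= {(off, par) for off in comp}
    remaining = [d for d in dyads if (d[0], d[1]) not in consumed]
    return components, inferred_sires, inferred_dams, remaining


def infer_by_ratio(
    remaining_dyads: Sequence[tuple[str, str, str]], rho: float
) -> tuple[int, int]:
    """Scale missing-parent counts by the pedigree's dam:sire ratio.

    With D_d distinct known dams among missing-sire dyads and S_d distinct
    known sires among missing-dam dyads, the inferred counterparts are
    x = round(D_d / rho) sires and y = round(S_d * rho) dams, so that the
    dam:sire ratio with the inferred individuals included is preserved.
    """
    if not rho > 0:
        raise ValueError("dam:sire ratio must be positive")
    known_dams = {par for _, par, psex in remaining_dyads if psex == "F"}
    known_sires = {par for _, par, psex in remaining_dyads if psex == "M"}
    x = _round_half_up(len(known_dams) / rho)
    y = _round_half_up(len(known_sires) * rho)
    return x, y


def mortality_correct(
    sires: int, dams: int, m_m: float = SIRE_MORTALITY, m_f: float = DAM_MORTALITY
) -> int:
    """Discount inferred parents by one year of sex-specific adult mortality.

    Inferred individuals are assumed to be at typical breeding age;
    N_in = round(sires * (1 - m_m)) + round(dams * (1 - m_f)), rounded per
    sex before summation.
    """
    if sires < 0 or dams < 0:
        raise ValueError("counts must be non-negative")
    return _round_half_up(sires * (1.0 - m_m)) + _round_half_up(dams * (1.0 - m_f))


def estimate_unsampled(
    n_in: int, n_s: int, b_s: int, strategy: str = "nonbreeder_fraction"
) -> int:
    """Estimate individuals that neither bred nor were sampled (N_un).

    The published account does not print a closed form, so the rule is
    configurable:

    - ``nonbreeder_fraction`` (default): apply the sampled non-breeder
      fraction to the inferred individuals, N_un = round(N_in (N_s-B_s)/N_s);
    - ``breeder_ratio``: N_un = round(N_in (N_s-B_s)/B_s);
    - ``none``: 0.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    if strategy == "none" or n_in == 0:
        return 0
    if b_s <= 0:
        raise ValueError("B_s must be positive for the ratio strategies")
    if strategy == "nonbreeder_fraction":
        return _round_half_up(n_in * (n_s - b_s) / n_s)
    return _round_half_up(n_in * (n_s - b_s) / b_s)


@dataclass
class CreResult:
    """Pedigree-based population estimate with its components and bounds."""

    n_s: int
    b_s: int
    n_dyads: int
    fs_inferred_sires: int
    fs_inferred_dams: int
    ratio_inferred_sires: int
    ratio_inferred_dams: int
    n_in: int
    n_un: int
    n_hat: int
    lower_bound: int
    upper_bound: int
    rho: float
    m_f: float
    m_m: float
    strategy: str
    fs_components: list[list[str]] = field(default_factory=list)

    @property
    def inferred_sires(self) -> int:
        return self.fs_inferred_sires + self.ratio_inferred_sires

    @property
    def inferred_dams(self) -> int:
        return self.fs_inferred_dams + self.ratio_inferred_dams

    @property
    def pct_increase_over_count(self) -> int:
        return percentage_increase(self.n_hat, self.n_s)

    def summary(self) -> str:
        lines = [
            "Pedigree-based population estimate",
            "=" * 44,
            f"Sampled genotypes (N_s)             {self.n_s:>8d}",
            f"Known breeders (B_s)                {self.b_s:>8d}",
            f"Parent-offspring dyads              {self.n_dyads:>8d}",
            f"Dam:sire ratio (rho)                {self.rho:>8.2f}",
            f"Full-sib inferred sires/dams        {self.fs_inferred_sires:>4d} / {self.fs_inferred_dams:<4d}",
            f"Ratio-method inferred sires/dams    {self.ratio_inferred_sires:>4d} / {self.ratio_inferred_dams:<4d}",
            f"Inferred after mortality (N_in)     {self.n_in:>8d}",
            f"Unsampled non-breeders (N_un)       {self.n_un:>8d}   [{self.strategy}]",
            f"Population estimate (N_hat)         {self.n_hat:>8d}",
            f"Bounds [N_s, dyads no-mortality]    [{self.lower_bound}, {self.upper_bound}]",
            f"Increase over genotype count        {self.pct_increase_over_count:>7d}%",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_s": self.n_s,
            "b_s": self.b_s,
            "n_dyads": self.n_dyads,
            "fs_inferred_sires": self.fs_inferred_sires,
            "fs_inferred_dams": self.fs_inferred_dams,
            "ratio_inferred_sires": self.ratio_inferred_sires,
            "ratio_inferred_dams": self.ratio_inferred_dams,
            "n_in": self.n_in,
            "n_un": self.n_un,
            "n_hat": self.n_hat,
            "lower_bound": self.lower_bound,
            "upper_bound": self.upper_bound,
            "rho": self.rho,
            "m_f": self.m_f,
            "m_m": self.m_m,
            "strategy": self.strategy,
            "pct_increase_over_count": self.pct_increase_over_count,
        }


def percentage_increase(n_hat: float, n_s: float) -> int:
    """Estimate's percentage gain over the raw genotype count, to integer %."""
    if n_s <= 0:
        raise ValueError("genotype count must be positive")
    return _round_half_up(100.0 * (n_hat - n_s) / n_s)


def cre_estimate(inputs: CreInputs, strategy: str = "nonbreeder_fraction") -> CreResult:
    """Full pedigree-based estimate: FS screen -> ratio -> mortality -> N_un."""
    components, fs_sires, fs_dams, remaining = screen_fullsib_dyads(
        inputs.dyads, inputs.relatedness, inputs.fs_threshold
    )
    ratio_sires, ratio_dams = infer_by_ratio(remaining, inputs.rho)
    n_in = mortality_correct(
        fs_sires + ratio_sires, fs_dams + ratio_dams, m_m=inputs.m_m, m_f=inputs.m_f
    )
    n_un = estimate_unsampled(n_in, inputs.n_s, inputs.b_s, strategy) if inputs.b_s else 0
    n_hat = inputs.n_s + n_in + n_un
    n_dyads = len(inputs.dyads)
    ub_un = (
        estimate_unsampled(n_dyads, inputs.n_s, inputs.b_s, strategy)
        if inputs.b_s
        else 0
    )
    return CreResult(
        n_s=inputs.n_s,
        b_s=inputs.b_s,
        n_dyads=n_dyads,
        fs_inferred_sires=fs_sires,
        fs_inferred_dams=fs_dams,
        ratio_inferred_sires=ratio_sires,
        ratio_inferred_dams=ratio_dams,
        n_in=n_in,
        n_un=n_un,
        n_hat=n_hat,
        lower_bound=inputs.n_s,
        upper_bound=inputs.n_s + n_dyads + ub_un,
        rho=inputs.rho,
        m_f=inputs.m_f,
        m_m=inputs.m_m,
        strategy=strategy,
        fs_components=components,
    )


class CreelRosenblattModel:
    """Pedigree-based population-size model in the model/results idiom.

    Built from a reconstructed pedigree (and optionally the relatedness
    matrix used for the full-sibling screen); ``fit`` returns a
    :class:`CreResult`.
    """

    def __init__(
        self,
        pedigree: PedigreeResult,
        relatedness: RelatednessMatrix | None = None,
        m_f: float = DAM_MORTALITY,
        m_m: float = SIRE_MORTALITY,
        fs_threshold: float = FS_THRESHOLD,
    ):
        self.inputs = CreInputs.from_pedigree(
            pedigree, relatedness, m_f=m_f, m_m=m_m, fs_threshold=fs_threshold
        )

    def fit(self, strategy: str = "nonbreeder_fraction") -> CreResult:
        return cre_estimate(self.inputs, strategy=strategy)


# --------------------------------------------------------------------------
# rarefaction / accumulation-curve estimator
# --------------------------------------------------------------------------


def accumulation_counts(sample_to_individual: Sequence) -> np.ndarray:
    """y_i = number of distinct individuals among the first i samples."""
    seq = list(sample_to_individual)
    if not seq:
        raise ValueError("empty sample sequence")
    seen: set = set()
    out = np.empty(len(seq), dtype=int)
    for i, s in enumerate(seq):
        seen.add(s)
        out[i] = len(seen)
    return out


class SaturationFit(NamedTuple):
    a: float
    b: float
    converged: bool
    degenerate: bool


def fit_saturation(
    xs, ys, xtol: float = 1e-8, max_iter: int = 500, divergence_factor: float = 50.0
) -> SaturationFit:
    """Least-squares fit of y = a x / (b + x).

    Initialized at a0 = max(y), b0 = median(x).  Constant y is degenerate;
    a fit whose asymptote runs away beyond ``divergence_factor * max(y)``
    (the near-linear, unsaturated regime where a and b are jointly
    unidentifiable) is flagged unconverged.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size < 3:
        raise ValueError("need at least three points")
    if np.any(np.diff(xs) <= 0):
        raise ValueError("xs must be strictly increasing")
    if np.allclose(ys, ys[0]):
        return SaturationFit(float("nan"), float("nan"), False, True)

    def resid(theta):
        a, b = theta
        return a * xs / (b + xs) - ys

    x0 = np.array([float(ys.max()), float(np.median(xs))])
    try:
        res = least_squares(
            resid,
            x0,
            bounds=([1e-9, 1e-9], [np.inf, np.inf]),
            xtol=xtol,
            max_nfev=max_iter * 2,
        )
    except Exception:
        return SaturationFit(float("nan"), float("nan"), False, False)
    a, b = float(res.x[0]), float(res.x[1])
    converged = bool(res.success) and b > 0 and a <= divergence_factor * float(ys.max())
    return SaturationFit(a, b, converged, False)


@dataclass
class RarefactionFit:
    """Ensemble rarefaction estimate over random sample orderings."""

    asymptotes: np.ndarray  # converged asymptotes, one per retained ordering
    slopes_b: np.ndarray
    mean_a: float
    n_iter: int
    n_converged: int
    n_samples: int
    n_unique: int

    @property
    def below_observed(self) -> bool:
        """Flag: the estimate should not undershoot the observed count."""
        return self.mean_a < self.n_unique

    def summary(self) -> str:
        lines = [
            "Rarefaction (accumulation-curve) estimate",
            "=" * 44,
            f"Samples                             {self.n_samples:>8d}",
            f"Unique genotypes observed           {self.n_unique:>8d}",
            f"Orderings fitted / converged        {self.n_iter:>4d} / {self.n_converged:<4d}",
            f"Mean asymptote (population size)    {self.mean_a:>10.1f}",
            f"Mean b (slope decline)              {float(np.mean(self.slopes_b)):>10.1f}",
        ]
        if self.below_observed:
            lines.append("WARNING: estimate below the observed unique-genotype count")
        return "\n".join(lines)


def rarefaction_estimate(
    sample_to_individual: Sequence,
    n_iter: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RarefactionFit:
    """Repeat the saturation fit over ``n_iter`` random sampling orders.

    The mean of the converged asymptotes is the population estimate; raises
    if no ordering yields a converged fit (e.g. every individual sampled
    exactly once, where the curve is the identity line).
    """
    seq = list(sample_to_individual)
    uniq = len(set(seq))
    if uniq < 2:
        raise ValueError("need at least two distinct individuals")
    rng = rng or np.random.default_rng(seed)
    xs = np.arange(1, len(seq) + 1, dtype=float)
    a_vals, b_vals = [], []
    n_done = 0
    for _ in range(n_iter):
        order = rng.permutation(len(seq))
        ys = accumulation_counts([seq[i] for i in order])
        fit = fit_saturation(xs, ys)
        n_done += 1
        if fit.converged:
            a_vals.append(fit.a)
            b_vals.append(fit.b)
    if not a_vals:
        raise RuntimeError("no rarefaction ordering produced a converged fit")
    return RarefactionFit(
        asymptotes=np.array(a_vals),
        slopes_b=np.array(b_vals),
        mean_a=float(np.mean(a_vals)),
        n_iter=n_done,
        n_converged=len(a_vals),
        n_samples=len(seq),
        n_unique=uniq,
    )


class RarefactionModel:
    """Model/results front end for the accumulation-curve estimator."""

    def __init__(self, sample_to_individual: Sequence):
        self.sample_to_individual = list(sample_to_individual)

    @classmethod
    def from_sample_set(cls, sample_set) -> "RarefactionModel":
        return cls([s.individual_id for s in sample_set.samples])

    def fit(self, n_iter: int = 100, seed: int | None = None) -> RarefactionFit:
        return rarefaction_estimate(self.sample_to_individual, n_iter=n_iter, seed=seed)
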