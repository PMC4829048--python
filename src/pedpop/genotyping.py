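"""From raw fecal-sample calls to identified individuals.

Stages: per-sample QC (>70 called assays), species and sex assignment from
the mt/Y/X assays, single-linkage genotype matching into unique individuals,
majority-rule consensus genotypes, and median spatial centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import networkx as nx
import numpy as np
import pandas as pd

from .panel import (
    CALL_TO_DOSAGE,
    CALLED,
    DOSAGE_TO_CALL,
    MISSING,
    MarkerPanel,
    UNCALLED,
)


class Sex(str, Enum):
    FEMALE = "F"
    MALE = "M"
    UNKNOWN = "U"


@dataclass(frozen=True)
class SexAssignment:
    """Species confirmation plus sex call for one sample or consensus."""

    species_confirmed: bool
    sex: Sex

    def __post_init__(self) -> None:
        if not self.species_confirmed and self.sex is not Sex.UNKNOWN:
            raise ValueError("sex can only be called on species-confirmed samples")


def qc_sample(sample, min_loci: int = 70, autosomal_only: bool = False) -> bool:
    """Pass iff the sample amplified for strictly more than `min_loci` assays.

    By default all 96 assays count toward the threshold; set
    ``autosomal_only`` to restrict the count to the autosomal SNPs.
    """
    n = int(np.sum(np.asarray(sample.auto_calls) != MISSING))
    if not autosomal_only:
        n += int(np.sum(sample.mt_called)) + int(np.sum(sample.y_called)) + int(
            np.sum(sample.x_called)
        )
    return n > min_loci


def assign_species_sex(obj=None, *, mt: int | None = None, y: int | None = None,
                       x: int | None = None) -> SexAssignment:
    """Apply the species/sex criteria to mt/Y/X call counts.

    Rules, in order: species confirmed (bear) iff >= 3 of 4 mt assays called;
    male iff >= 3 of 4 Y assays called; female iff zero Y calls and >= 2 of 3
    X assays called.  Anything else (e.g. 1-2 Y calls) is left UNKNOWN -- the
    criteria are one-sided by design so that a poorly amplified male is never
    mistaken for a female.
    """
    if obj is not None:
        mt = int(np.sum(obj.mt_called))
        y = int(np.sum(obj.y_called))
        x = int(np.sum(obj.x_called))
    if mt is None or y is None or x is None:
        raise ValueError("provide a sample object or mt/y/x counts")
    if mt < 3:
        return SexAssignment(species_confirmed=False, sex=Sex.UNKNOWN)
    if y >= 3:
        return SexAssignment(species_confirmed=True, sex=Sex.MALE)
    if y == 0 and x >= 2:
        return SexAssignment(species_confirmed=True, sex=Sex.FEMALE)
    return SexAssignment(species_confirmed=True, sex=Sex.UNKNOWN)


def median_center(locations) -> tuple[float, float]:
    """Componentwise median of planar locations (robust home-range proxy)."""
    arr = np.asarray(locations, dtype=float)
    if arr.size == 0:
        raise ValueError("median_center requires at least one location")
    arr = arr.reshape(-1, 2)
    return float(np.median(arr[:, 0])), float(np.median(arr[:, 1]))


@dataclass
class IdentifiedIndividual:
    individual_id: str
    member_sample_ids: list[str]
    consensus_genotype: np.ndarray  # (L,) dosage, -1 missing
    n_loci_called: int
    sex: SexAssignment
    median_center: tuple[float, float]
    mt_calls: int = 0
    y_calls: int = 0
    x_calls: int = 0
    sex_conflict: bool = False
    latent_ids: list[str] = field(default_factory=list)


def _consensus(calls: np.ndarray) -> np.ndarray:
    """Majority call per locus over member samples; ties -> missing."""
    n_loci = calls.shape[1]
    out = np.full(n_loci, MISSING, dtype=np.int8)
    counts = np.stack([(calls == g).sum(axis=0) for g in (0, 1, 2)])  # (3, L)
    top = counts.max(axis=0)
    n_top = (counts == top[None, :]).sum(axis=0)
    winner = counts.argmax(axis=0)
    ok = (top > 0) & (n_top == 1)
    out[ok] = winner[ok]
    return out


def match_samples(
    samples,
    max_mismatch: int = 2,
    min_overlap: int = 40,
) -> list[IdentifiedIndividual]:
    """Cluster QC-passed samples into individuals by single linkage.

    Two samples link iff they share at least ``min_overlap`` co-called
    autosomal loci and disagree at no more than ``max_mismatch`` of them.
    Each connected component becomes one individual carrying the
    majority-rule consensus genotype, an any-sample union of the sex-assay
    calls, and the componentwise median of the sample locations.  Clusters
    whose member samples receive conflicting sex calls are flagged, never
    silently merged away.
    """
    samples = list(samples)
    n = len(samples)
    if n == 0:
        return []
    G = np.stack([np.asarray(s.auto_calls, dtype=np.int8) for s in samples])
    called = G != MISSING

    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for i in range(n):
        both = called[i] & called[i + 1 :]
        overlap = both.sum(axis=1)
        mm = ((G[i] != G[i + 1 :]) & both).sum(axis=1)
        links = np.nonzero((overlap >= min_overlap) & (mm <= max_mismatch))[0]
        for j in links:
            graph.add_edge(i, int(i + 1 + j))

    clusters = sorted(
        (sorted(c, key=lambda k: samples[k].sample_id) for c in nx.connected_components(graph)),
        key=lambda c: samples[c[0]].sample_id,
    )

    out: list[IdentifiedIndividual] = []
    for idx, members in enumerate(clusters):
        sub = G[members]
        cons = _consensus(sub)
        mt = np.zeros(len(samples[members[0]].mt_called), dtype=bool)
        yy = np.zeros(len(samples[members[0]].y_called), dtype=bool)
        xx = np.zeros(len(samples[members[0]].x_called), dtype=bool)
        locs = []
        sexes = set()
        for k in members:
            s = samples[k]
            mt |= np.asarray(s.mt_called, dtype=bool)
            yy |= np.asarray(s.y_called, dtype=bool)
            xx |= np.asarray(s.x_called, dtype=bool)
            locs.append(s.location)
            a = assign_species_sex(mt=int(np.sum(s.mt_called)), y=int(np.sum(s.y_called)),
                                   x=int(np.sum(s.x_called)))
            if a.sex is not Sex.UNKNOWN:
                sexes.add(a.sex)
        assignment = assign_species_sex(mt=int(mt.sum()), y=int(yy.sum()), x=int(xx.sum()))
        conflict = len(sexes) > 1
        if conflict:
            warnings.warn(
                f"cluster {idx} merges samples with conflicting sex calls", stacklevel=2
            )
        latent = sorted({getattr(samples[k], "individual_id", None) for k in members}
                        - {None})
        out.append(
            IdentifiedIndividual(
                individual_id=f"G{idx + 1:04d}",
                member_sample_ids=[samples[k].sample_id for k in members],
                consensus_genotype=cons,
                n_loci_called=int(np.sum(cons != MISSING)),
                sex=assignment,
                median_center=median_center(locs),
                mt_calls=int(mt.sum()),
                y_calls=int(yy.sum()),
                x_calls=int(xx.sum()),
                sex_conflict=conflict,
                latent_ids=latent,
            )
        )
    return out


@dataclass
class IndividualTable:
    """Array-backed table of identified individuals.

    The canonical in-memory container handed to the relatedness, parentage
    and experiment stages: ids, consensus genotypes (dosage of the reference
    allele, -1 missing), sex codes ('F'/'M'/'U'), median centers and sample
    counts.
    """

    ids: list[str]
    genotypes: np.ndarray  # (n, L) int8
    sex: np.ndarray  # (n,) '<U1'
    centers: np.ndarray  # (n, 2) float
    locus_ids: list[str]
    n_samples: np.ndarray | None = None
    latent_ids: list[str] | None = None  # ground-truth ids, synthetic data only
    members: list[list[str]] | None = None  # member sample ids per individual

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.sex = np.asarray(self.sex, dtype="<U1")
        self.centers = np.asarray(self.centers, dtype=float).reshape(len(self.ids), 2)

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, indices) -> "IndividualTable":
        indices = np.asarray(indices)
        return IndividualTable(
            ids=[self.ids[i] for i in indices],
            genotypes=self.genotypes[indices],
            sex=self.sex[indices],
            centers=self.centers[indices],
            locus_ids=self.locus_ids,
            n_samples=None if self.n_samples is None else self.n_samples[indices],
            latent_ids=None
            if self.latent_ids is None
            else [self.latent_ids[i] for i in indices],
            members=None
            if self.members is None
            else [self.members[i] for i in indices],
        )

    @classmethod
    def from_identified(
        cls, individuals: list[IdentifiedIndividual], panel: MarkerPanel
    ) -> "IndividualTable":
        return cls(
            ids=[ind.individual_id for ind in individuals],
            genotypes=np.stack([ind.consensus_genotype for ind in individuals])
            if individuals
            else np.empty((0, panel.n_autosomal), dtype=np.int8),
            sex=np.array([ind.sex.sex.value for ind in individuals], dtype="<U1"),
            centers=np.array([ind.median_center for ind in individuals], dtype=float)
            if individuals
            else np.empty((0, 2)),
            locus_ids=list(panel.autosomal_ids),
            n_samples=np.array([len(ind.member_sample_ids) for ind in individuals]),
            latent_ids=[
                ind.latent_ids[0] if len(ind.latent_ids) == 1 else ""
                for ind in individuals
            ],
            members=[list(ind.member_sample_ids) for ind in individuals],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "individual_id": self.ids,
                "n_samples": self.n_samples
                if self.n_samples is not None
                else np.zeros(len(self.ids), dtype=int),
                "sex": self.sex,
                "x_median": self.centers[:, 0],
                "y_median": self.centers[:, 1],
            }
        )
        calls = pd.DataFrame(
            [[DOSAGE_TO_CALL[int(g)] for g in row] for row in self.genotypes],
            columns=self.locus_ids,
        )
        return pd.concat([df, calls], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "IndividualTable":
        df = pd.read_csv(path)
        meta = {"individual_id", "n_samples", "sex", "x_median", "y_median"}
        locus_ids = [c for c in df.columns if c not in meta]
        geno = np.array(
            [[CALL_TO_DOSAGE[str(v)] for v in df[c]] for c in locus_ids], dtype=np.int8
        ).T
        return cls(
            ids=df["individual_id"].astype(str).tolist(),
            genotypes=geno,
            sex=df["sex"].astype(str).to_numpy(),
            centers=df[["x_median", "y_median"]].to_numpy(),
            locus_ids=locus_ids,
            n_samples=df["n_samples"].to_numpy()
            if "n_samples" in df
            else None,
        )


def identify_individuals(
    sample_set,
    min_loci: int = 70,
    max_mismatch: int = 2,
    min_overlap: int = 40,
    require_species: bool = True,
) -> IndividualTable:
    """QC + species filter + matching, returning an :class:`IndividualTable`."""
    kept = [s for s in sample_set.samples if qc_sample(s, min_loci=min_loci)]
    if require_species:
        kept = [
            s
            for s in kept
            if assign_species_sex(
                mt=int(np.sum(s.mt_called)),
                y=int(np.sum(s.y_called)),
                x=int(np.sum(s.x_called)),
            ).species_confirmed
        ]
    individuals = match_samples(kept, max_mismatch=max_mismatch, min_overlap=min_overlap)
    return IndividualTable.from_identified(individuals, sample_set.panel)
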