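"""The 96-assay SNP marker panel.

The panel mirrors the layout used for noninvasive brown-bear genotyping:
85 biallelic autosomal SNPs (used for individual identification, relatedness
and parentage), 4 mitochondrial SNPs (species confirmation), 4 Y-chromosome
and 3 X-chromosome assays (sex determination).

Autosomal calls are encoded internally as the dosage of the reference
allele A: ``2`` = AA, ``1`` = AB, ``0`` = BB, ``-1`` = missing ("NN" on
disk).  The haploid/sex assays are presence calls: "C" = called, "-" =
uncalled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_AUTOSOMAL = 85
N_MT = 4
N_Y = 4
N_X = 3
N_ASSAYS = N_AUTOSOMAL + N_MT + N_Y + N_X  # 96

MISSING = -1

#: genotype dosage -> CSV call string
DOSAGE_TO_CALL = {2: "AA", 1: "AB", 0: "BB", MISSING: "NN"}
CALL_TO_DOSAGE = {v: k for k, v in DOSAGE_TO_CALL.items()}

CALLED = "C"
UNCALLED = "-"


@dataclass(frozen=True)
class MarkerPanel:
    """Composition of the genotyping panel.

    Parameters
    ----------
    autosomal_freqs
        Population frequency of the reference (A) allele at each autosomal
        locus; all must lie strictly inside (0, 1).
    """

    autosomal_freqs: np.ndarray
    autosomal_ids: tuple[str, ...] = ()
    mt_ids: tuple[str, ...] = tuple(f"mt{i+1}" for i in range(N_MT))
    y_ids: tuple[str, ...] = tuple(f"y{i+1}" for i in range(N_Y))
    x_ids: tuple[str, ...] = tuple(f"x{i+1}" for i in range(N_X))

    def __post_init__(self) -> None:
        freqs = np.asarray(self.autosomal_freqs, dtype=float)
        object.__setattr__(self, "autosomal_freqs", freqs)
        if freqs.ndim != 1 or freqs.size == 0:
            raise ValueError("autosomal_freqs must be a non-empty 1-D array")
        if np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
            raise ValueError("allele frequencies must be strictly inside (0, 1)")
        if not self.autosomal_ids:
            ids = tuple(f"a{i+1:02d}" for i in range(freqs.size))
            object.__setattr__(self, "autosomal_ids", ids)
        if len(self.autosomal_ids) != freqs.size:
            raise ValueError("autosomal_ids length must match autosomal_freqs")
        if len(self.mt_ids) != N_MT or len(self.y_ids) != N_Y or len(self.x_ids) != N_X:
            raise ValueError(
                f"panel must carry {N_MT} mt, {N_Y} Y and {N_X} X assays"
            )

    @property
    def n_autosomal(self) -> int:
        return int(self.autosomal_freqs.size)

    @property
    def n_assays(self) -> int:
        return self.n_autosomal + N_MT + N_Y + N_X

    @property
    def assay_ids(self) -> tuple[str, ...]:
        return self.autosomal_ids + self.mt_ids + self.y_ids + self.x_ids


def default_panel(
    freqs: np.ndarray | None = None,
    n_autosomal: int = N_AUTOSOMAL,
    seed: int | None = 0,
    low: float = 0.1,
    high: float = 0.9,
) -> MarkerPanel:
    """Build a panel; allele frequencies drawn uniform on (`low`, `high`).

    A fixed default seed makes the stock panel reproducible across sessions.
    """
    if freqs is None:
        rng = np.random.default_rng(seed)
        freqs = rng.uniform(low, high, size=n_autosomal)
    return MarkerPanel(autosomal_freqs=np.asarray(freqs, dtype=float))
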