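"""Configuration types for the synthetic experiment generator.

The single-cell design mirrors a three-arm myeloid culture experiment:
control PBMC-derived monocytes (C), cytokine-treated MDSC-like cells (T),
and cytokine-treated cells subsequently serum-starved (TS), collected from
several donors.  Planted co-expression modules carry condition responses
that are either retained (stress-tolerant) or lost/reversed
(stress-sensitive) in the resistant subpopulation of the starved arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

GROUPS = ("C", "T", "TS")

#: canonical tolerance classes for planted modules
TOLERANCE_CLASSES = ("tolerant", "sensitive", "neutral")


@dataclass
class PlantedModule:
    """A planted co-expression module with condition responses.

    Parameters
    ----------
    name:
        Module label used in ground-truth tables.
    gene_ids:
        Member gene identifiers; module gene sets must be disjoint.
    latent_loading:
        Strength of the shared per-cell latent factor added to member
        genes' log-means (controls within-module correlation).
    effect_T:
        Natural-log mean shift of member genes in cytokine-treated (T)
        cells relative to control.
    effect_TS_resistant:
        Shift in resistant cells of the starved (TS) arm.
    effect_TS_other:
        Shift in non-resistant TS cells.
    tolerance_class:
        "tolerant" (induction retained in resistant cells), "sensitive"
        (induction lost or reversed in resistant cells) or "neutral".
    """

    name: str
    gene_ids: list[str]
    latent_loading: float = 0.5
    effect_T: float = 0.0
    effect_TS_resistant: float = 0.0
    effect_TS_other: float = 0.0
    tolerance_class: str = "neutral"

    def validate(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"module {self.name!r} has no genes")
        if self.latent_loading < 0:
            raise ValueError("latent_loading must be nonnegative")
        if self.tolerance_class not in TOLERANCE_CLASSES:
            raise ValueError(f"unknown tolerance_class {self.tolerance_class!r}")
        if self.tolerance_class == "tolerant":
            if not (self.effect_T > 0 and self.effect_TS_resistant > 0):
                raise ValueError(
                    "tolerant module requires effect_T > 0 and effect_TS_resistant > 0"
                )
        if self.tolerance_class == "sensitive":
            if not (self.effect_T > 0 and self.effect_TS_resistant <= 0):
                raise ValueError(
                    "sensitive module requires effect_T > 0 and effect_TS_resistant <= 0"
                )


@dataclass
class CnvBlock:
    """A planted copy-number block: contiguous genes on one chromosome whose
    mean expression is multiplied by 2**log2_dosage in carrier cells."""

    chromosome: str
    start_gene: int  # index of the first spanned gene *within* the chromosome
    length: int      # number of consecutive genes spanned
    log2_dosage: float

    def validate(self) -> None:
        if self.start_gene < 0 or self.length < 1:
            raise ValueError("cnv block needs start_gene >= 0 and length >= 1")


@dataclass
class SimConfig:
    """Full configuration of the synthetic single-cell and bulk experiments.

    ``n_cells_per_group`` is per donor and per condition group.  Bulk
    parameters describe a multi-source paired MDSC/control design with
    per-source batch offsets.
    """

    n_donors: int = 2
    n_cells_per_group: int = 500
    groups: tuple[str, ...] = GROUPS
    n_genes: int = 1000
    modules: list[PlantedModule] = field(default_factory=list)
    resistant_fraction: float = 0.3
    cnv_blocks: list[CnvBlock] = field(default_factory=list)
    nb_dispersion: float = 0.3
    library_size_lognormal: tuple[float, float] = (math.log(5000.0), 0.3)
    # bulk design
    n_sources: int = 5
    n_samples_per_arm: int = 4
    source_batch_sd: float = 0.5
    # extra generator knobs (defaults are the study conditions; see docs)
    n_chromosomes: int = 5
    base_logmean_sd: float = 1.0
    cnv_carrier_fraction: float = 0.5
    bulk_noise_sd: float = 0.5
    n_sensitive_sources: int = 2
    # starvation-stress response mounted by non-resistant starved cells:
    # a fixed program of background genes with mixed-sign log shifts
    stress_gene_ids: list[str] = field(default_factory=list)
    ts_stress_sd: float = 1.0
    # identity markers of the resistant subpopulation (its CD52-like
    # surface-marker program), again mixed-sign fixed shifts
    resistant_marker_gene_ids: list[str] = field(default_factory=list)
    resistant_marker_sd: float = 1.0
    seed: int = 0

    # ------------------------------------------------------------------
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def chromosome_of(self) -> list[str]:
        """Evenly partition genes over synthetic chromosomes, in order."""
        per = self.n_genes // self.n_chromosomes
        chroms = []
        for i in range(self.n_genes):
            c = min(i // per, self.n_chromosomes - 1)
            chroms.append(f"chr{c + 1}")
        return chroms

    def validate(self) -> None:
        if tuple(self.groups) != GROUPS:
            raise ValueError(f"groups must be exactly {GROUPS}")
        for name, v in (
            ("n_donors", self.n_donors),
            ("n_cells_per_group", self.n_cells_per_group),
            ("n_genes", self.n_genes),
            ("n_chromosomes", self.n_chromosomes),
        ):
            if v < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.resistant_fraction <= 1.0:
            raise ValueError("resistant_fraction must be in [0, 1]")
        if not 0.0 <= self.cnv_carrier_fraction <= 1.0:
            raise ValueError("cnv_carrier_fraction must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.source_batch_sd < 0 or self.bulk_noise_sd < 0:
            raise ValueError("batch/noise sd must be nonnegative")
        if self.ts_stress_sd < 0 or self.resistant_marker_sd < 0:
            raise ValueError("program parameters must be nonnegative")
        ids = self.gene_ids()
        gene_set = set(ids)
        stress_set = set(self.stress_gene_ids)
        marker_set = set(self.resistant_marker_gene_ids)
        if not (stress_set | marker_set) <= gene_set:
            raise ValueError("stress/marker programs reference unknown genes")
        if stress_set & marker_set:
            raise ValueError("stress and resistant-marker programs must not overlap")
        stress = stress_set | marker_set
        seen: set[str] = set()
        for mod in self.modules:
            mod.validate()
            members = set(mod.gene_ids)
            if not members <= gene_set:
                raise ValueError(f"module {mod.name!r} references unknown genes")
            if members & seen:
                raise ValueError("module gene sets must be disjoint")
            if members & stress:
                raise ValueError("module gene sets must not overlap the stress program")
            seen |= members
        chroms = self.chromosome_of()
        per_chrom: dict[str, int] = {}
        for c in chroms:
            per_chrom[c] = per_chrom.get(c, 0) + 1
        for blk in self.cnv_blocks:
            blk.validate()
            if blk.chromosome not in per_chrom:
                raise ValueError(f"unknown chromosome {blk.chromosome!r}")
            if blk.start_gene + blk.length > per_chrom[blk.chromosome]:
                raise ValueError(
                    f"cnv block exceeds gene range of {blk.chromosome}"
                )

    def to_dict(self) -> dict:
        return asdict(self)


def default_config(seed: int = 0) -> SimConfig:
    """The default study conditions: 2 donors x 3 groups x 500 cells,
    1000 genes on 5 chromosomes, three planted 50-gene modules (tolerant /
    sensitive / neutral) and one 150-gene copy-number gain on chr1."""
    ids = [f"G{i:04d}" for i in range(1000)]
    # planted programs are interleaved across chr2-chr5 (genes 200-999):
    # co-expressed or co-regulated genes are not genomically contiguous,
    # so expression programs must not masquerade as copy-number segments.
    # Within each 16-gene block: 0=tolerant, 1=sensitive, 2=neutral,
    # 3-5=stress program, 6-7=resistant markers, rest background.
    tol_ids = [ids[200 + 16 * k] for k in range(50)]
    sen_ids = [ids[201 + 16 * k] for k in range(50)]
    neu_ids = [ids[202 + 16 * k] for k in range(50)]
    modules = [
        # the tolerant program is the stronger, defining MDSC axis: its
        # induction is fully retained in resistant starved cells
        PlantedModule(
            name="planted_tolerant",
            gene_ids=tol_ids,
            latent_loading=0.5,
            effect_T=1.5,
            effect_TS_resistant=1.5,
            effect_TS_other=0.0,
            tolerance_class="tolerant",
        ),
        # the sensitive program is weaker and is lost specifically in
        # resistant cells under starvation
        PlantedModule(
            name="planted_sensitive",
            gene_ids=sen_ids,
            latent_loading=0.5,
            effect_T=0.9,
            effect_TS_resistant=0.0,
            effect_TS_other=0.9,
            tolerance_class="sensitive",
        ),
        PlantedModule(
            name="planted_neutral",
            gene_ids=neu_ids,
            latent_loading=0.5,
            effect_T=0.0,
            effect_TS_resistant=0.0,
            effect_TS_other=0.0,
            tolerance_class="neutral",
        ),
    ]
    stress_ids = [ids[200 + 16 * k + o] for k in range(50) for o in (3, 4, 5)]
    marker_ids = [ids[200 + 16 * k + o] for k in range(50) for o in (6, 7)]
    cnv = [CnvBlock(chromosome="chr1", start_gene=25, length=150, log2_dosage=1.0)]
    return SimConfig(
        modules=modules,
        cnv_blocks=cnv,
        stress_gene_ids=stress_ids,
        resistant_marker_gene_ids=marker_ids,
        seed=seed,
    )
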