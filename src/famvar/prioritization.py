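"""Family-based rare-variant prioritization cascade.

The cascade mirrors the filtering scheme used to go from a whole-genome
callset of affected relatives down to a short list of candidate variants:

1. coding / canonical-splice consequence with at least one high-confidence
   carrier call (read-support thresholds);
2. non-synonymous (drops synonymous changes);
3. shared by every index patient of at least one family AND protein-altering
   (truncating consequences always; missense only at highly conserved
   positions, phyloP >= 3.0 by default);
4. rare: at most 0.001 in every reference panel where the variant is seen at
   all, and absent from the in-house exome database;
5. candidate-gene categorization (GWAS IBD loci > PID genes > IBD pathway
   genes > novel protein-altering);
6. optional externally supplied pass-list (stand-in for a manual IGV review)
   and cap-list (genotyping-panel capacity), both skipped by default.

Each stage only removes variants, so the per-stage counts are monotonically
non-increasing; stages 3 and 4 are independent per-variant predicates and
therefore commute.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError, DataError, ValidationError
from .variant_io import (AnnotatedVariant, Family, GenePanels, Pedigree,
                         VariantCall, VariantKey)

__all__ = [
    "QualityThresholds",
    "RarityThresholds",
    "ConservationThreshold",
    "CascadeConfig",
    "CascadeReport",
    "is_high_confidence",
    "is_protein_altering",
    "is_rare",
    "shared_in_family",
    "assign_candidate_category",
    "run_cascade",
    "index_calls",
]

log = logging.getLogger(__name__)

#: Consequence classes treated as protein-truncating / splice-disrupting;
#: these count as protein-altering regardless of conservation.
TRUNCATING = frozenset({"frameshift", "nonsense", "canonical_splice"})

#: Coding or canonical-splice classes (everything the cascade considers).
CODING = frozenset({"frameshift", "nonsense", "canonical_splice", "missense",
                    "synonymous"})

CATEGORIES = ("gwas", "pid", "pathway", "novel", "none")


@dataclass(frozen=True)
class QualityThresholds:
    """Read-support thresholds for a high-confidence call."""

    min_total_reads: int = 10
    min_variant_reads: int = 5
    min_variant_fraction: float = 0.20

    def __post_init__(self) -> None:
        if self.min_total_reads <= 0 or self.min_variant_reads <= 0:
            raise ConfigError("read-count thresholds must be positive")
        if not (0.0 < self.min_variant_fraction <= 1.0):
            raise ConfigError("min_variant_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class RarityThresholds:
    """Reference-panel frequency ceiling plus in-house absence requirement."""

    max_maf: float = 0.001
    require_inhouse_absent: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_maf <= 1.0):
            raise ConfigError("max_maf must lie in [0, 1]")


@dataclass(frozen=True)
class ConservationThreshold:
    """phyloP floor applied to missense variants only.

    ``missing_phylop_passes`` controls missense variants with no phyloP
    annotation: excluded by default (conservative), retained if set.
    """

    min_phylop: float = 3.0
    missing_phylop_passes: bool = False


@dataclass(frozen=True)
class CascadeConfig:
    quality: QualityThresholds = QualityThresholds()
    rarity: RarityThresholds = RarityThresholds()
    conservation: ConservationThreshold = ConservationThreshold()
    #: Optional surrogate for a manual visual review: keys that may pass.
    pass_list: frozenset[VariantKey] | None = None
    #: Optional genotyping-panel capacity list: keys that fit on the assay.
    cap_list: frozenset[VariantKey] | None = None


# ---------------------------------------------------------------------------
# Predicates
# ---------------------------------------------------------------------------

def is_high_confidence(call: VariantCall, t: QualityThresholds | None = None) -> bool:
    """True iff the call's read support meets all three thresholds
    (total reads, variant reads, variant-read fraction)."""
    t = t or QualityThresholds()
    if call.total_reads == 0:
        if call.genotype != "missing":
            raise DataError(
                f"{call.key.unique_id}/{call.sample}: non-missing genotype "
                f"with zero total reads")
        return False
    return (call.total_reads >= t.min_total_reads
            and call.variant_reads >= t.min_variant_reads
            and call.variant_reads / call.total_reads >= t.min_variant_fraction)


def is_protein_altering(v: AnnotatedVariant,
                        c: ConservationThreshold | None = None) -> bool:
    """True for truncating/splice consequences unconditionally; for missense
    only at conserved positions (phyloP >= threshold); false otherwise."""
    c = c or ConservationThreshold()
    if v.consequence in TRUNCATING:
        return True
    if v.consequence == "missense":
        if v.phylop is None:
            log.info("predicate=protein_altering variant=%s reason=missing_phylop "
                     "kept=%s", v.key.unique_id, c.missing_phylop_passes)
            return c.missing_phylop_passes
        return v.phylop >= c.min_phylop
    return False


def is_rare(v: AnnotatedVariant, t: RarityThresholds | None = None) -> bool:
    """True iff every reference-panel frequency that is present is at most
    ``max_maf`` (absent counts as passing) and, when required, the variant is
    absent from the in-house database."""
    t = t or RarityThresholds()
    if t.require_inhouse_absent and v.inhouse_present:
        return False
    return all(f <= t.max_maf for f in v.panel_frequencies)


def index_calls(calls: Iterable[VariantCall]) -> dict[tuple[VariantKey, str], VariantCall]:
    """Index calls by (variant key, sample id) for the sharing predicate."""
    return {(c.key, c.sample): c for c in calls}


def shared_in_family(
    key: VariantKey,
    family: Family,
    call_index: Mapping[tuple[VariantKey, str], VariantCall],
    quality: QualityThresholds | None = None,
) -> bool:
    """True iff *every* index patient of the family carries at least one
    alternate allele at ``key`` with a high-confidence call. An index
    patient with no call record (or a missing genotype) is a non-carrier.
    """
    quality = quality or QualityThresholds()
    for member in family.index_patients:
        call = call_index.get((key, member.sample_id))
        if call is None:
            log.info("predicate=shared variant=%s family=%s sample=%s "
                     "reason=no_call", key.unique_id, family.family_id,
                     member.sample_id)
            return False
        if not call.carries_alt or not is_high_confidence(call, quality):
            return False
    return True


def shared_in_any_family(
    key: VariantKey,
    pedigree: Pedigree,
    call_index: Mapping[tuple[VariantKey, str], VariantCall],
    quality: QualityThresholds | None = None,
) -> bool:
    return any(shared_in_family(key, fam, call_index, quality)
               for fam in pedigree.families)


def assign_candidate_category(
    v: AnnotatedVariant,
    panels: GenePanels,
    conservation: ConservationThreshold | None = None,
) -> str:
    """Categorize a variant: ``gwas`` > ``pid`` > ``pathway`` by gene-panel
    membership, else ``novel`` when protein-altering, else ``none``."""
    gene = v.gene.upper()
    if gene in panels.gwas_ibd:
        return "gwas"
    if gene in panels.pid:
        return "pid"
    if gene in panels.pathway:
        return "pathway"
    if is_protein_altering(v, conservation):
        return "novel"
    return "none"


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

@dataclass
class CascadeReport:
    """Ordered per-stage surviving counts plus the final categorized set."""

    stages: list[tuple[str, int]]
    final: dict[VariantKey, str]            # key -> candidate category
    exclusions: dict[VariantKey, str]       # key -> stage that removed it

    @property
    def final_keys(self) -> set[VariantKey]:
        return set(self.final)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["stage\tremaining_variants"]
        lines += [f"{name}\t{count}" for name, count in self.stages]
        Path(path).write_text("\n".join(lines) + "\n")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "stages": [{"stage": n, "remaining": c} for n, c in self.stages],
            "final": [{"unique_id": k.unique_id, "category": cat}
                      for k, cat in sorted(self.final.items())],
            "exclusions": [{"unique_id": k.unique_id, "stage": s}
                           for k, s in sorted(self.exclusions.items())],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def run_cascade(
    variants: Sequence[AnnotatedVariant],
    calls: Iterable[VariantCall],
    pedigree: Pedigree,
    panels: GenePanels,
    config: CascadeConfig | None = None,
    swap_shared_rare: bool = False,
) -> CascadeReport:
    """Apply the full prioritization cascade and record per-stage counts.

    ``swap_shared_rare`` applies the rarity filter before the family-sharing
    filter; the two stages are independent predicates, so the final set is
    unchanged (the intermediate count differs). Exposed for exactly that
    verification.
    """
    config = config or CascadeConfig()
    if not pedigree.families:
        raise ValidationError("empty pedigree")
    call_index = index_calls(calls)

    current: list[AnnotatedVariant] = list(variants)
    stages: list[tuple[str, int]] = [("all_variants", len(current))]
    exclusions: dict[VariantKey, str] = {}

    def apply(name: str, predicate) -> None:
        nonlocal current
        survivors = []
        for v in current:
            if predicate(v):
                survivors.append(v)
            else:
                exclusions[v.key] = name
        current = survivors
        stages.append((name, len(current)))
        log.info("stage=%s remaining=%d", name, len(current))

    def has_high_conf_carrier(v: AnnotatedVariant) -> bool:
        return any(
            (c := call_index.get((v.key, s))) is not None
            and c.carries_alt and is_high_confidence(c, config.quality)
            for s in pedigree.sample_ids)

    apply("coding_splice_quality",
          lambda v: v.consequence in CODING and has_high_conf_carrier(v))
    apply("non_synonymous", lambda v: v.consequence != "synonymous")

    def shared_protein_altering(v: AnnotatedVariant) -> bool:
        return (is_protein_altering(v, config.conservation)
                and shared_in_any_family(v.key, pedigree, call_index,
                                         config.quality))

    def rare(v: AnnotatedVariant) -> bool:
        return is_rare(v, config.rarity)

    if swap_shared_rare:
        apply("rare", rare)
        apply("family_shared_protein_altering", shared_protein_altering)
    else:
        apply("family_shared_protein_altering", shared_protein_altering)
        apply("rare", rare)

    categories = {v.key: assign_candidate_category(v, panels, config.conservation)
                  for v in current}
    apply("candidate_gene", lambda v: categories[v.key] != "none")

    if config.pass_list is not None:
        apply("pass_list", lambda v: v.key in config.pass_list)
    if config.cap_list is not None:
        apply("cap_list", lambda v: v.key in config.cap_list)

    final = {v.key: categories[v.key] for v in current}
    return CascadeReport(stages=stages, final=final, exclusions=exclusions)
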