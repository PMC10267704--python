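"""Seeded generators for every input the pipeline consumes.

Two generators are provided:

* :func:`simulate_families` emulates the *post-calling* output of a
  family-based whole-genome study at desk size: an annotated multi-sample
  VCF over affected relatives, the pedigree, candidate-gene panels, and a
  truth manifest. Planted variants are given to every index patient of
  their designated families with read support that satisfies the quality
  model; every background variant is explicitly assigned one prioritization
  predicate to fail, so a cascade run over the output has an exact expected
  answer (the manifest), not a probabilistic one.

* :func:`simulate_replication` draws a case-control genotyping cohort with
  a known control carrier frequency and true odds ratio. Case carrier
  probability follows from the odds transform p = r f / (1 - f + r f), so
  the configured odds ratio is exactly the estimand of the association
  module. Genotyping missingness is applied per subject, independently.

Both generators are fully deterministic for a fixed seed: all sampling
goes through one ``numpy.random.Generator`` in a fixed order, and all
writers emit byte-identical text.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from . import prioritization as pz
from .variant_io import (AnnotatedVariant, Family, GenePanels, Pedigree,
                         PedigreeMember, VariantCall, VariantKey, write_gene_panel,
                         write_annotation_table, write_pedigree, write_vcf)

__all__ = [
    "PlantedVariant",
    "FamilySimConfig",
    "ReplicationSimConfig",
    "FamilySimulation",
    "simulate_families",
    "simulate_replication",
    "case_carrier_probability",
]

#: Designed failure categories for background variants, in cycling order.
FAILURE_CATEGORIES = ("noncoding", "synonymous", "low_quality", "not_shared",
                      "low_phylop_missense", "common_maf", "inhouse_present")

_MAF_FIELDS = ("maf_dbsnp", "maf_esp", "maf_exac", "maf_1kg")


@dataclass(frozen=True)
class PlantedVariant:
    """A causal variant to plant: gene, consequence, conservation, panel
    membership, the families whose index patients all share it, and optional
    frequency/in-house attributes (used to plant *designed-to-fail*
    variants, e.g. a too-common allele)."""

    gene: str
    consequence: str = "frameshift"
    phylop: float | None = None
    panel: str | None = "pathway"            # gwas / pid / pathway / None
    families: tuple[int, ...] = (0,)         # indices into the pedigree
    mafs: tuple[tuple[str, float], ...] = () # e.g. (("maf_exac", 0.01),)
    inhouse_present: bool = False


@dataclass(frozen=True)
class FamilySimConfig:
    """Study-shaped defaults: 12 families of 2 affected index patients, and
    one planted rare frameshift in an innate-immunity pathway gene shared by
    the index patients of a single family."""

    seed: int
    n_families: int = 12
    members_per_family: int = 2
    n_background_variants: int = 500
    planted: tuple[PlantedVariant, ...] = (
        PlantedVariant(gene="SIRPB1", consequence="frameshift",
                       panel="pathway", families=(6,)),
    )
    # reference-panel frequency model for background variants:
    # point mass at "absent" + log-uniform frequency otherwise
    maf_absent_prob: float = 0.4
    maf_log_min: float = 1e-5
    maf_log_max: float = 0.05
    # read-depth model: gamma-Poisson (negative-binomial-shaped) counts
    mean_depth: float = 30.0
    depth_dispersion: float = 5.0
    base_error_rate: float = 0.002

    def __post_init__(self) -> None:
        if self.n_families <= 0 or self.members_per_family <= 0:
            raise ConfigError("family counts must be positive")
        if self.n_background_variants == 0 and not self.planted:
            raise ConfigError("nothing to simulate: no background variants "
                              "and no planted variants")
        if self.n_background_variants < 0:
            raise ConfigError("n_background_variants must be >= 0")
        for p in self.planted:
            if any(i < 0 or i >= self.n_families for i in p.families):
                raise ConfigError(f"planted variant {p.gene}: family index "
                                  f"out of range")
            if p.panel not in (None, "gwas", "pid", "pathway"):
                raise ConfigError(f"unknown panel {p.panel!r}")


@dataclass
class TruthRecord:
    unique_id: str
    gene: str
    survives: bool
    reason: str  # "planted" for survivors; failing predicate otherwise


@dataclass
class FamilySimulation:
    """In-memory simulation output plus writers for the on-disk formats."""

    variants: list[AnnotatedVariant]
    calls: list[VariantCall]
    pedigree: Pedigree
    panels: GenePanels
    truth: list[TruthRecord]

    @property
    def expected_survivors(self) -> set[str]:
        return {t.unique_id for t in self.truth if t.survives}

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out / "cohort.vcf",
            "pedigree": out / "pedigree.tsv",
            "annotations": out / "annotations.tsv",
            "gwas_panel": out / "panel_gwas.txt",
            "pid_panel": out / "panel_pid.txt",
            "pathway_panel": out / "panel_pathway.txt",
            "truth": out / "truth.json",
        }
        write_vcf(paths["vcf"], self.variants, self.calls)
        write_pedigree(paths["pedigree"], self.pedigree)
        write_annotation_table(paths["annotations"], self.variants)
        write_gene_panel(paths["gwas_panel"], self.panels.gwas_ibd)
        write_gene_panel(paths["pid_panel"], self.panels.pid)
        write_gene_panel(paths["pathway_panel"], self.panels.pathway)
        payload = [{"unique_id": t.unique_id, "gene": t.gene,
                    "survives": t.survives, "reason": t.reason}
                   for t in self.truth]
        paths["truth"].write_text(json.dumps(payload, indent=2) + "\n")
        return paths


def _make_pedigree(cfg: FamilySimConfig) -> Pedigree:
    families = []
    for i in range(cfg.n_families):
        fid = f"F{i + 1:02d}"
        members = tuple(
            PedigreeMember(sample_id=f"{fid}-{j + 1:02d}", affected=True,
                           index_patient=True, kinship="affected relative")
            for j in range(cfg.members_per_family))
        families.append(Family(fid, members))
    return Pedigree(tuple(families))


_BASES = ("A", "C", "G", "T")


def _depth(rng: np.random.Generator, cfg: FamilySimConfig) -> int:
    lam = rng.gamma(cfg.depth_dispersion, cfg.mean_depth / cfg.depth_dispersion)
    return int(rng.poisson(lam))


def _carrier_reads(rng: np.random.Generator, cfg: FamilySimConfig,
                   high_quality: bool) -> tuple[int, int]:
    """(total, variant) reads for a het carrier. When ``high_quality``,
    counts are nudged up to the minimum the quality thresholds demand."""
    depth = _depth(rng, cfg)
    if high_quality:
        depth = max(depth, 10)
        var = int(rng.binomial(depth, 0.5))
        var = max(var, 5, math.ceil(0.2 * depth))
        return depth, min(var, depth)
    depth = min(depth, 8)  # fails the >= 10 total-reads bound
    var = min(int(rng.binomial(max(depth, 1), 0.5)), depth, 4)
    return depth, var


def _noncarrier_reads(rng: np.random.Generator,
                      cfg: FamilySimConfig) -> tuple[int, int]:
    depth = max(_depth(rng, cfg), 1)
    var = int(min(rng.binomial(depth, cfg.base_error_rate), depth // 5))
    return depth, var


def _background_mafs(rng: np.random.Generator, cfg: FamilySimConfig,
                     rare: bool) -> dict[str, float | None]:
    """Draw the four reference-panel frequencies. ``rare`` restricts the
    log-uniform draw below the 0.001 rarity ceiling so that designed
    failures elsewhere do not accidentally fail the rarity stage too."""
    out: dict[str, float | None] = {}
    hi = 0.001 if rare else cfg.maf_log_max
    for name in _MAF_FIELDS:
        if rng.random() < cfg.maf_absent_prob:
            out[name] = None
        else:
            lo = cfg.maf_log_min
            out[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return out


def _first_failing_predicate(v: AnnotatedVariant, pedigree: Pedigree,
                             call_index, config: pz.CascadeConfig) -> str | None:
    """Direct per-variant predicate evaluation, mirroring the cascade order;
    returns None when the variant survives everything."""
    if v.consequence not in pz.CODING:
        return "noncoding"
    if not any((c := call_index.get((v.key, s))) is not None and c.carries_alt
               and pz.is_high_confidence(c, config.quality)
               for s in pedigree.sample_ids):
        return "quality"
    if v.consequence == "synonymous":
        return "synonymous"
    if not pz.is_protein_altering(v, config.conservation):
        return "not_protein_altering"
    if not pz.shared_in_any_family(v.key, pedigree, call_index, config.quality):
        return "not_shared"
    if not pz.is_rare(v, config.rarity):
        return "rarity"
    return None


def simulate_families(cfg: FamilySimConfig) -> FamilySimulation:
    """Generate the annotated family cohort with planted causal variants.

    The truth manifest is computed by direct predicate evaluation on the
    generated records (not by running the cascade), so it is an independent
    statement of which variants must survive.
    """
    rng = np.random.default_rng(cfg.seed)
    pedigree = _make_pedigree(cfg)

    # gene panels: planted genes on their designated panel + decoy symbols
    panels = {"gwas": {"NOD2", "TNFSF15", "LSP1", "ZPBP2", "SDCCAG3", "MUC19"},
              "pid": {"BTK", "WAS", "FOXP3", "IL2RG"},
              "pathway": {"SIRPB1", "TLR4", "MYD88", "ELANE"}}
    for p in cfg.planted:
        if p.panel is not None:
            panels[p.panel].add(p.gene.upper())

    variants: list[AnnotatedVariant] = []
    calls: list[VariantCall] = []
    designed: list[tuple[AnnotatedVariant, str]] = []  # (variant, category)

    def add_calls(v: AnnotatedVariant, carrier_samples: set[str],
                  high_quality: bool) -> None:
        for fam in pedigree.families:
            for m in fam.members:
                if m.sample_id in carrier_samples:
                    total, var = _carrier_reads(rng, cfg, high_quality)
                    calls.append(VariantCall(v.key, m.sample_id, "het",
                                             total, var))
                else:
                    total, var = _noncarrier_reads(rng, cfg)
                    calls.append(VariantCall(v.key, m.sample_id, "hom_ref",
                                             total, var))

    def site(i: int, indel: bool) -> VariantKey:
        chrom = f"chr{(i % 22) + 1}"
        pos = 100_000 + 997 * i  # spaced, deterministic, strictly increasing
        ref_i = int(rng.integers(0, 4))
        ref = _BASES[ref_i]
        if indel:
            ins = _BASES[int(rng.integers(0, 4))]
            return VariantKey(chrom, pos, ref, ref + ins)
        alt = _BASES[(ref_i + 1 + int(rng.integers(0, 3))) % 4]
        return VariantKey(chrom, pos, ref, alt)

    # --- planted variants -------------------------------------------------
    for j, p in enumerate(cfg.planted):
        key = site(10_000_000 + j, indel=p.consequence == "frameshift")
        mafs = {name: None for name in _MAF_FIELDS}
        mafs.update(dict(p.mafs))
        phylop = p.phylop
        if p.consequence == "missense" and phylop is None:
            phylop = float(rng.uniform(3.0, 9.0))
        v = AnnotatedVariant(key=key, gene=p.gene.upper(),
                             consequence=p.consequence, phylop=phylop,
                             inhouse_present=p.inhouse_present, **mafs)
        variants.append(v)
        carriers = {m.sample_id
                    for i in p.families
                    for m in pedigree.families[i].index_patients}
        add_calls(v, carriers, high_quality=True)
        designed.append((v, "planted"))

    # --- designed-failure background variants -----------------------------
    categories = [c for c in FAILURE_CATEGORIES
                  if not (c == "not_shared" and cfg.members_per_family < 2)]
    passing_csq = ("frameshift", "nonsense", "canonical_splice", "missense")
    for i in range(cfg.n_background_variants):
        cat = categories[i % len(categories)]
        csq = passing_csq[int(rng.integers(0, len(passing_csq)))]
        phylop: float | None = float(rng.uniform(3.0, 9.0))
        mafs = _background_mafs(rng, cfg, rare=True)
        inhouse = False
        if cat == "noncoding":
            csq, phylop = "other", None
        elif cat == "synonymous":
            csq, phylop = "synonymous", None
        elif cat == "low_phylop_missense":
            csq, phylop = "missense", float(rng.uniform(0.0, 2.9))
        elif cat == "common_maf":
            which = _MAF_FIELDS[int(rng.integers(0, 4))]
            mafs[which] = float(rng.uniform(0.002, cfg.maf_log_max))
        elif cat == "inhouse_present":
            inhouse = True
        key = site(i, indel=csq == "frameshift")
        v = AnnotatedVariant(key=key, gene=f"BG{i + 1:05d}", consequence=csq,
                             phylop=phylop, inhouse_present=inhouse, **mafs)
        variants.append(v)

        fam = pedigree.families[i % cfg.n_families]
        if cat == "not_shared":
            carriers = {fam.index_patients[0].sample_id}
        else:
            carriers = {m.sample_id for m in fam.index_patients}
        add_calls(v, carriers, high_quality=cat != "low_quality")
        designed.append((v, cat))

    # --- truth manifest by direct predicate evaluation --------------------
    gene_panels = GenePanels(gwas_ibd=frozenset(panels["gwas"]),
                             pid=frozenset(panels["pid"]),
                             pathway=frozenset(panels["pathway"]))
    config = pz.CascadeConfig()
    call_index = pz.index_calls(calls)
    truth = []
    for v, cat in designed:
        fail = _first_failing_predicate(v, pedigree, call_index, config)
        survives = fail is None
        truth.append(TruthRecord(v.key.unique_id, v.gene, survives,
                                 "planted" if survives else fail))
    return FamilySimulation(variants=variants, calls=calls, pedigree=pedigree,
                            panels=gene_panels, truth=truth)


# ---------------------------------------------------------------------------
# Replication cohort
# ---------------------------------------------------------------------------

def case_carrier_probability(control_freq: float, odds_ratio: float) -> float:
    """Odds transform: p = r f / (1 - f + r f)."""
    return odds_ratio * control_freq / (1 - control_freq
                                        + odds_ratio * control_freq)


@dataclass(frozen=True)
class ReplicationSimConfig:
    """Replication-cohort generator: cohort sizes default to the 381/381
    case-control design; carrier status is drawn per subject."""

    seed: int
    control_carrier_freq: float
    true_odds_ratio: float
    n_cases: int = 381
    n_controls: int = 381
    missing_rate: float = 0.0
    n_variants: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.control_carrier_freq < 1.0):
            raise ConfigError("control_carrier_freq must lie in [0, 1)")
        if self.true_odds_ratio <= 0:
            raise ConfigError("true_odds_ratio must be > 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.n_cases <= 0 or self.n_controls <= 0 or self.n_variants <= 0:
            raise ConfigError("cohort sizes must be positive")
        p = case_carrier_probability(self.control_carrier_freq,
                                     self.true_odds_ratio)
        if p >= 1.0:
            raise ConfigError("implied case carrier probability >= 1")


def simulate_replication(
    cfg: ReplicationSimConfig,
) -> tuple[pd.DataFrame, dict]:
    """Draw per-variant genotype tallies for a case-control cohort.

    Returns the long-form tally table consumed by
    :func:`famvar.association.associate_all` plus a truth manifest with the
    configured parameters and the implied case carrier probability.
    Carriers are emitted as heterozygotes; the dominant-model collapse is
    invariant to the het/hom-alt split at these frequencies.
    """
    rng = np.random.default_rng(cfg.seed)
    p_case = case_carrier_probability(cfg.control_carrier_freq,
                                      cfg.true_odds_ratio)
    rows = []
    for i in range(cfg.n_variants):
        vid = f"chr1:{1_000_000 + i}A>G"
        n_case = int(cfg.n_cases - rng.binomial(cfg.n_cases, cfg.missing_rate))
        n_ctrl = int(cfg.n_controls - rng.binomial(cfg.n_controls,
                                                   cfg.missing_rate))
        case_car = int(rng.binomial(n_case, p_case))
        ctrl_car = int(rng.binomial(n_ctrl, cfg.control_carrier_freq))
        for group, car, total in (("case", case_car, n_case),
                                  ("control", ctrl_car, n_ctrl)):
            rows.append({"variant": vid, "gene": f"GENE{i + 1:04d}",
                         "rs_id": ".", "group": group, "genotype": "het",
                         "count": car})
            rows.append({"variant": vid, "gene": f"GENE{i + 1:04d}",
                         "rs_id": ".", "group": group, "genotype": "hom_ref",
                         "count": total - car})
    table = pd.DataFrame(rows)
    truth = {
        "control_carrier_freq": cfg.control_carrier_freq,
        "true_odds_ratio": cfg.true_odds_ratio,
        "case_carrier_prob": p_case,
        "n_cases": cfg.n_cases,
        "n_controls": cfg.n_controls,
        "missing_rate": cfg.missing_rate,
        "n_variants": cfg.n_variants,
    }
    return table, truth
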