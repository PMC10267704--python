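"""Readers, writers and domain types for the formats the pipeline touches.

The pipeline consumes annotated multi-sample VCFs (genotype, depth and
allele-depth per sample; site-level annotations in INFO), a pedigree table,
plain-text gene-panel lists, and tabular annotation/report files. Everything
site-level is keyed by :class:`VariantKey`, whose string form matches the
``chrom:posREF>ALT`` unique-id dialect used in replication genotyping tables
(e.g. ``chr20:1546854GC>GCC``).

VCF access goes through :mod:`pysam`; multi-allelic sites are decomposed
into one record per alternate allele on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

from .errors import FormatError, ParseError, ValidationError

__all__ = [
    "CONSEQUENCES",
    "GENOTYPES",
    "DEFAULT_ANNOTATION_KEYS",
    "VariantKey",
    "VariantCall",
    "AnnotatedVariant",
    "PedigreeMember",
    "Family",
    "Pedigree",
    "GenePanels",
    "read_vcf",
    "write_vcf",
    "read_pedigree",
    "write_pedigree",
    "read_gene_panel",
    "write_gene_panel",
    "read_annotation_table",
    "write_annotation_table",
]

#: Recognised consequence classes, most to least severe for our purposes.
CONSEQUENCES = ("frameshift", "nonsense", "canonical_splice", "missense",
                "synonymous", "other")

#: Collapsed diploid genotype classes.
GENOTYPES = ("hom_ref", "het", "hom_alt", "missing")

#: Default INFO keys carrying the site annotations.
DEFAULT_ANNOTATION_KEYS: Mapping[str, str] = {
    "gene": "GENE",
    "consequence": "CSQ",
    "phylop": "PHYLOP",
    "maf_dbsnp": "AF_DBSNP",
    "maf_esp": "AF_ESP",
    "maf_exac": "AF_EXAC",
    "maf_1kg": "AF_1KG",
    "inhouse": "INHOUSE",
}

_ALLELE_RE = re.compile(r"^[ACGT]+$")
# unique id: "chr20:1546854GC>GCC"; whitespace between position and alleles is
# tolerated on input (some tables print "chr19:10079057 TCACAGG...>T").
_UNIQUE_ID_RE = re.compile(
    r"^\s*(?P<chrom>[\w.]+):(?P<pos>\d+)\s*(?P<ref>[ACGTacgt]+)>(?P<alt>[ACGTacgt]+)\s*$"
)


@dataclass(frozen=True, order=True)
class VariantKey:
    """A single alternate allele at a genomic site, VCF-style (1-based,
    anchored-base indels)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not _ALLELE_RE.match(allele):
                raise ValidationError(
                    f"{name} allele must be a non-empty uppercase ACGT string, got {allele!r}")
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt are identical at {self.chrom}:{self.pos}")

    @property
    def unique_id(self) -> str:
        """``chrom:posREF>ALT`` string form."""
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"

    @classmethod
    def from_unique_id(cls, text: str) -> "VariantKey":
        m = _UNIQUE_ID_RE.match(text)
        if m is None:
            raise ParseError(f"not a variant unique id: {text!r}")
        return cls(m["chrom"], int(m["pos"]), m["ref"].upper(), m["alt"].upper())

    def trimmed(self) -> "VariantKey":
        """Minimal representation: drop shared trailing bases, then shared
        leading bases (advancing ``pos``), always keeping one base of each
        allele. Deterministic canonicalization of anchored indels; full
        left-alignment additionally needs the reference sequence and is out
        of scope here.
        """
        ref, alt, pos = self.ref, self.alt, self.pos
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt, pos = ref[1:], alt[1:], pos + 1
        if (ref, alt, pos) == (self.ref, self.alt, self.pos):
            return self
        return VariantKey(self.chrom, pos, ref, alt)


@dataclass(frozen=True)
class VariantCall:
    """One variant allele in one sample: collapsed genotype plus the read
    evidence backing it."""

    key: VariantKey
    sample: str
    genotype: str
    total_reads: int
    variant_reads: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValidationError(f"unknown genotype class {self.genotype!r}")
        if not (0 <= self.variant_reads <= self.total_reads):
            raise ValidationError(
                f"{self.key.unique_id}/{self.sample}: need 0 <= variant_reads "
                f"({self.variant_reads}) <= total_reads ({self.total_reads})")

    @property
    def carries_alt(self) -> bool:
        return self.genotype in ("het", "hom_alt")


@dataclass(frozen=True)
class AnnotatedVariant:
    """Site-level record: gene, consequence class, conservation and
    reference-panel allele frequencies.

    A frequency of ``None`` means the variant is *absent from that panel*,
    which the rarity filter treats differently from an observed frequency.
    """

    key: VariantKey
    gene: str
    consequence: str
    phylop: float | None = None
    maf_dbsnp: float | None = None
    maf_esp: float | None = None
    maf_exac: float | None = None
    maf_1kg: float | None = None
    inhouse_present: bool = False

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValidationError(f"unknown consequence class {self.consequence!r}")
        for name in ("maf_dbsnp", "maf_esp", "maf_exac", "maf_1kg"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1] at {self.key.unique_id}")

    @property
    def panel_frequencies(self) -> tuple[float, ...]:
        """The reference-panel frequencies that are present (non-absent)."""
        return tuple(v for v in (self.maf_dbsnp, self.maf_esp, self.maf_exac,
                                 self.maf_1kg) if v is not None)


@dataclass(frozen=True)
class PedigreeMember:
    sample_id: str
    affected: bool
    index_patient: bool
    kinship: str = ""


@dataclass(frozen=True)
class Family:
    family_id: str
    members: tuple[PedigreeMember, ...]

    @property
    def index_patients(self) -> tuple[PedigreeMember, ...]:
        return tuple(m for m in self.members if m.index_patient)


@dataclass(frozen=True)
class Pedigree:
    """Families of study subjects with affected/index flags.

    Invariants enforced on construction: globally unique sample ids and at
    least one index patient per family.
    """

    families: tuple[Family, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for fam in self.families:
            if not fam.index_patients:
                raise ValidationError(f"family {fam.family_id} has no index patient")
            for m in fam.members:
                if m.sample_id in seen:
                    raise ValidationError(f"duplicate sample id {m.sample_id}")
                seen.add(m.sample_id)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(m.sample_id for f in self.families for m in f.members)

    def __len__(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class GenePanels:
    """Candidate-gene panels: IBD GWAS loci, primary-immunodeficiency genes
    and IBD-pathway genes (innate immune / immune system / neutrophil
    degranulation)."""

    gwas_ibd: frozenset[str] = frozenset()
    pid: frozenset[str] = frozenset()
    pathway: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name in ("gwas_ibd", "pid", "pathway"):
            panel = frozenset(s.upper() for s in getattr(self, name))
            if any(not s for s in panel):
                raise ValidationError(f"empty symbol in panel {name}")
            object.__setattr__(self, name, panel)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f", ".", ""}


def _parse_flag(value: object) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ParseError(f"cannot interpret {value!r} as a boolean flag")


def _info_for_alt(value: object, alt_index: int, n_alts: int) -> str | None:
    """Pick the per-alt element out of an INFO value that may be a scalar,
    a tuple, or a comma-joined string."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        items = [str(v) for v in value]
    else:
        items = str(value).split(",")
    if len(items) == n_alts:
        text = items[alt_index]
    elif len(items) == 1:
        text = items[0]
    else:
        raise ParseError(
            f"INFO value {value!r} has {len(items)} elements for {n_alts} alt alleles")
    text = text.strip()
    return None if text in (".", "", "None") else text


def _info_get(rec: "pysam.VariantRecord", key: str) -> object | None:
    """INFO lookup tolerant of keys absent from both record and header
    (pysam raises on undeclared keys)."""
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def _collapse_genotype(gt: Sequence[int | None] | None, alt_allele_index: int) -> str:
    if gt is None or all(a is None for a in gt):
        return "missing"
    n_alt = sum(1 for a in gt if a == alt_allele_index)
    if n_alt == 0:
        return "hom_ref"
    if n_alt == 1 and len([a for a in gt if a is not None]) > 1:
        return "het"
    return "hom_alt"


def read_vcf(
    path: str | Path,
    annotation_keys: Mapping[str, str] | None = None,
) -> tuple[list[AnnotatedVariant], list[VariantCall]]:
    """Read an annotated multi-sample VCF.

    Returns one :class:`AnnotatedVariant` per (site, alt allele) — multi-
    allelic sites are decomposed — and one :class:`VariantCall` per sample
    per (site, alt allele). Per-sample ``GT`` is required; ``DP``/``AD``
    supply the read evidence (a sample missing both is treated as an
    evidence-free call with zero reads).

    ``annotation_keys`` maps the logical annotation names (``gene``,
    ``consequence``, ``phylop``, ``maf_dbsnp``, ``maf_esp``, ``maf_exac``,
    ``maf_1kg``, ``inhouse``) to INFO keys; defaults to
    :data:`DEFAULT_ANNOTATION_KEYS`.
    """
    keys = dict(DEFAULT_ANNOTATION_KEYS)
    if annotation_keys:
        keys.update(annotation_keys)
    path = Path(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"{path}: cannot open as VCF: {exc}") from exc

    variants: list[AnnotatedVariant] = []
    calls: list[VariantCall] = []
    with vcf:
        samples = list(vcf.header.samples)
        for rec_no, rec in enumerate(vcf, start=1):
            try:
                alts = rec.alts or ()
                if "GT" not in rec.format:
                    raise FormatError(
                        f"{path} record {rec_no} ({rec.chrom}:{rec.pos}): no GT field")
                n_alts = len(alts)
                for alt_i, alt in enumerate(alts):
                    key = VariantKey(rec.chrom, rec.pos, str(rec.ref).upper(),
                                     str(alt).upper())
                    phylop = _info_for_alt(_info_get(rec, keys["phylop"]), alt_i, n_alts)
                    inhouse_raw = _info_get(rec, keys["inhouse"])
                    if isinstance(inhouse_raw, bool):  # declared as Flag
                        inhouse = inhouse_raw
                    elif inhouse_raw is None:
                        inhouse = False
                    else:
                        text = _info_for_alt(inhouse_raw, alt_i, n_alts)
                        inhouse = _parse_flag(text) if text is not None else False
                    kwargs: dict[str, float | None] = {}
                    for fld in ("maf_dbsnp", "maf_esp", "maf_exac", "maf_1kg"):
                        text = _info_for_alt(_info_get(rec, keys[fld]), alt_i, n_alts)
                        kwargs[fld] = float(text) if text is not None else None
                    gene = _info_for_alt(_info_get(rec, keys["gene"]), alt_i, n_alts) or ""
                    csq = (_info_for_alt(_info_get(rec, keys["consequence"]), alt_i, n_alts)
                           or "other").lower()
                    if csq not in CONSEQUENCES:
                        csq = "other"
                    variants.append(AnnotatedVariant(
                        key=key, gene=gene.upper(), consequence=csq,
                        phylop=float(phylop) if phylop is not None else None,
                        inhouse_present=inhouse, **kwargs))

                    for sample in samples:
                        sm = rec.samples[sample]
                        gt = sm.get("GT")
                        genotype = _collapse_genotype(gt, alt_i + 1)
                        ad = sm.get("AD")
                        dp = sm.get("DP")
                        variant_reads = 0
                        if ad is not None and len(ad) > alt_i + 1 and ad[alt_i + 1] is not None:
                            variant_reads = int(ad[alt_i + 1])
                        if dp is not None:
                            total = int(dp)
                        elif ad is not None:
                            total = int(sum(a or 0 for a in ad))
                        else:
                            total = 0
                        total = max(total, variant_reads)
                        calls.append(VariantCall(key, sample, genotype, total,
                                                 variant_reads))
            except FormatError:
                raise
            except (ParseError, ValidationError) as exc:
                raise ParseError(f"{path} record {rec_no}: {exc}") from exc
    return variants, calls


def _fmt_opt(value: float | None) -> str:
    return "." if value is None else repr(float(value))


def write_vcf(
    path: str | Path,
    variants: Sequence[AnnotatedVariant],
    calls: Iterable[VariantCall],
    annotation_keys: Mapping[str, str] | None = None,
) -> None:
    """Write variants and per-sample calls as an uncompressed VCF 4.2 file.

    One biallelic record is written per :class:`AnnotatedVariant`, sorted by
    (chrom, pos, ref, alt); output is byte-deterministic for fixed input.
    """
    keys = dict(DEFAULT_ANNOTATION_KEYS)
    if annotation_keys:
        keys.update(annotation_keys)
    call_index: dict[tuple[VariantKey, str], VariantCall] = {}
    samples: list[str] = []
    for c in calls:
        call_index[(c.key, c.sample)] = c
        if c.sample not in samples:
            samples.append(c.sample)

    ordered = sorted(variants, key=lambda v: (v.key.chrom, v.key.pos, v.key.ref,
                                              v.key.alt))
    contigs = sorted({v.key.chrom for v in ordered})
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    for k in (keys["gene"], keys["consequence"]):
        lines.append(f'##INFO=<ID={k},Number=1,Type=String,Description="{k}">')
    for k in (keys["phylop"], keys["maf_dbsnp"], keys["maf_esp"], keys["maf_exac"],
              keys["maf_1kg"], keys["inhouse"]):
        lines.append(f'##INFO=<ID={k},Number=1,Type=String,Description="{k}">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t"
                 "FORMAT\t" + "\t".join(samples))

    gt_str = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}
    for v in ordered:
        info = ";".join([
            f"{keys['gene']}={v.gene or '.'}",
            f"{keys['consequence']}={v.consequence}",
            f"{keys['phylop']}={_fmt_opt(v.phylop)}",
            f"{keys['maf_dbsnp']}={_fmt_opt(v.maf_dbsnp)}",
            f"{keys['maf_esp']}={_fmt_opt(v.maf_esp)}",
            f"{keys['maf_exac']}={_fmt_opt(v.maf_exac)}",
            f"{keys['maf_1kg']}={_fmt_opt(v.maf_1kg)}",
            f"{keys['inhouse']}={1 if v.inhouse_present else 0}",
        ])
        cols = [v.key.chrom, str(v.key.pos), ".", v.key.ref, v.key.alt, ".",
                "PASS", info, "GT:DP:AD"]
        for s in samples:
            c = call_index.get((v.key, s))
            if c is None:
                cols.append("./.:0:0,0")
            else:
                ref_reads = c.total_reads - c.variant_reads
                cols.append(f"{gt_str[c.genotype]}:{c.total_reads}:"
                            f"{ref_reads},{c.variant_reads}")
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Pedigree / panels / annotation tables
# ---------------------------------------------------------------------------

_PED_REQUIRED = ("family_id", "sample_id", "affected", "index")


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a tab-separated pedigree with header
    ``family_id  sample_id  affected  index  [kinship]``."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValidationError(f"{path}: empty pedigree file")
    header = [h.strip() for h in lines[0].split("\t")]
    missing = [c for c in _PED_REQUIRED if c not in header]
    if missing:
        raise FormatError(f"{path}: pedigree header missing columns {missing}")
    col = {name: header.index(name) for name in header}
    families: dict[str, list[PedigreeMember]] = {}
    order: list[str] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) < len(_PED_REQUIRED):
            raise ParseError(f"{path} line {lineno}: expected >= 4 columns")
        fam = parts[col["family_id"]].strip()
        member = PedigreeMember(
            sample_id=parts[col["sample_id"]].strip(),
            affected=_parse_flag(parts[col["affected"]]),
            index_patient=_parse_flag(parts[col["index"]]),
            kinship=parts[col["kinship"]].strip() if "kinship" in col
            and len(parts) > col["kinship"] else "",
        )
        if fam not in families:
            families[fam] = []
            order.append(fam)
        families[fam].append(member)
    if not families:
        raise ValidationError(f"{path}: pedigree has no members")
    return Pedigree(tuple(Family(f, tuple(families[f])) for f in order))


def write_pedigree(path: str | Path, pedigree: Pedigree) -> None:
    lines = ["family_id\tsample_id\taffected\tindex\tkinship"]
    for fam in pedigree.families:
        for m in fam.members:
            lines.append(f"{fam.family_id}\t{m.sample_id}\t{int(m.affected)}\t"
                         f"{int(m.index_patient)}\t{m.kinship}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_panel(path: str | Path) -> frozenset[str]:
    """Read a plain-text gene panel: one symbol per line, ``#`` comments
    allowed. Symbols are uppercased and deduplicated; an effectively empty
    panel is an error."""
    path = Path(path)
    symbols = set()
    for ln in path.read_text().splitlines():
        text = ln.split("#", 1)[0].strip()
        if text:
            symbols.add(text.upper())
    if not symbols:
        raise ValidationError(f"{path}: gene panel contains no symbols")
    return frozenset(symbols)


def write_gene_panel(path: str | Path, symbols: Iterable[str]) -> None:
    Path(path).write_text("\n".join(sorted({s.upper() for s in symbols})) + "\n")


_ANNOT_COLUMNS = ("unique_id", "gene", "consequence", "phylop", "maf_dbsnp",
                  "maf_esp", "maf_exac", "maf_1kg", "inhouse")


def write_annotation_table(path: str | Path, variants: Sequence[AnnotatedVariant]) -> None:
    """Write site annotations as TSV (one row per alt allele)."""
    lines = ["\t".join(_ANNOT_COLUMNS)]
    for v in variants:
        lines.append("\t".join([
            v.key.unique_id, v.gene, v.consequence, _fmt_opt(v.phylop),
            _fmt_opt(v.maf_dbsnp), _fmt_opt(v.maf_esp), _fmt_opt(v.maf_exac),
            _fmt_opt(v.maf_1kg), str(int(v.inhouse_present)),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotation_table(path: str | Path) -> list[AnnotatedVariant]:
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValidationError(f"{path}: empty annotation table")
    header = lines[0].split("\t")
    if header != list(_ANNOT_COLUMNS):
        raise FormatError(f"{path}: unexpected annotation header {header}")
    out = []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != len(_ANNOT_COLUMNS):
            raise ParseError(f"{path} line {lineno}: expected "
                             f"{len(_ANNOT_COLUMNS)} columns")
        def opt(text: str) -> float | None:
            return None if text == "." else float(text)
        out.append(AnnotatedVariant(
            key=VariantKey.from_unique_id(parts[0]),
            gene=parts[1], consequence=parts[2], phylop=opt(parts[3]),
            maf_dbsnp=opt(parts[4]), maf_esp=opt(parts[5]), maf_exac=opt(parts[6]),
            maf_1kg=opt(parts[7]), inhouse_present=bool(int(parts[8]))))
    return out
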