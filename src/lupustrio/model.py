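"""Shared data model for trio whole-exome analysis.

Coordinates follow the VCF convention throughout: 1-based, fully closed.
Absent annotation fields are a distinct state (``None`` / ``*.ABSENT``),
never zero — a variant with no population-frequency entry is *novel* and
must be treated as rare by downstream frequency filters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Consequence(str, Enum):
    """Coding consequence of a variant on its gene."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_CANONICAL = "splice_canonical"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Consequence classes retained by the rare-variant screen: missense,
#: nonsense, coding indels and canonical (+/-1, +/-2) splice-site variants.
INCLUDED_CONSEQUENCES = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT_INDEL,
        Consequence.INFRAME_INDEL,
        Consequence.SPLICE_CANONICAL,
    }
)


class PolyPhen(str, Enum):
    PROBABLY_DAMAGING = "probably_damaging"
    POSSIBLY_DAMAGING = "possibly_damaging"
    BENIGN = "benign"
    ABSENT = "absent"


class Sift(str, Enum):
    DELETERIOUS = "deleterious"
    TOLERATED = "tolerated"
    ABSENT = "absent"


class ClinVarClass(str, Enum):
    P_LP = "P_LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"
    CI = "CI"
    ABSENT = "absent"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class Origin(str, Enum):
    """Inheritance origin of a variant observed in a proband."""

    PATERNAL = "paternal"
    MATERNAL = "maternal"
    BIPARENTAL_AMBIGUOUS = "biparental_ambiguous"
    DE_NOVO_GERMLINE = "de_novo_germline"
    DE_NOVO_MOSAIC_SUSPECT = "de_novo_mosaic_suspect"
    HOMOZYGOUS_RECESSIVE = "homozygous_recessive"
    COMPOUND_HET_PARTNER = "compound_het_partner"
    UNRESOLVED = "unresolved"


DE_NOVO_ORIGINS = frozenset({Origin.DE_NOVO_GERMLINE, Origin.DE_NOVO_MOSAIC_SUSPECT})


@dataclass(frozen=True)
class VariantRecord:
    """One annotated alternate allele.

    Multi-allelic VCF sites are decomposed upstream, so every record
    carries exactly one ``alt``. ``af_global`` / ``af_eas`` are gnomAD-style
    population allele frequencies; ``None`` means the variant has no entry
    in that reference panel (novel).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Optional[str] = None
    consequence: Consequence = Consequence.OTHER
    af_global: Optional[float] = None
    af_eas: Optional[float] = None
    polyphen: PolyPhen = PolyPhen.ABSENT
    sift: Sift = Sift.ABSENT
    cadd_phred: Optional[float] = None
    clinvar: ClinVarClass = ClinVarClass.ABSENT
    dbsnp: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.alt == self.ref:
            raise ValueError(f"alt equals ref ({self.ref}) at {self.chrom}:{self.pos}")
        for name in ("af_global", "af_eas"):
            af = getattr(self, name)
            if af is not None and not (0.0 <= af <= 1.0):
                raise ValueError(f"{name}={af} outside [0, 1]")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"cadd_phred must be non-negative, got {self.cadd_phred}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def vid(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class GenotypeCall:
    """Per-sample genotype with allele-depth evidence.

    ``vaf`` (variant allele fraction) is derived from allele depths and is
    ``None`` when no reads cover the site; germline heterozygotes sit near
    0.5, post-zygotic (mosaic) variants lower.
    """

    sample_id: str
    gt: Optional[tuple[int, int]]  # allele indices after decomposition, None = missing
    ad_ref: int = 0
    ad_alt: int = 0
    dp: int = 0
    gq: int = 0
    hemizygous: bool = False

    def __post_init__(self) -> None:
        if self.ad_ref < 0 or self.ad_alt < 0:
            raise ValueError("allele depths must be non-negative")
        if self.ad_ref + self.ad_alt > self.dp:
            raise ValueError(
                f"ad_ref+ad_alt ({self.ad_ref + self.ad_alt}) exceeds dp ({self.dp})"
            )

    @property
    def vaf(self) -> Optional[float]:
        denom = self.ad_ref + self.ad_alt
        if denom == 0:
            return None
        return self.ad_alt / denom

    @property
    def n_alt_alleles(self) -> Optional[int]:
        """0/1/2 alt-allele dosage, None if genotype missing."""
        if self.gt is None:
            return None
        return sum(1 for a in self.gt if a == 1)

    @property
    def carries_alt(self) -> bool:
        return self.gt is not None and 1 in self.gt

    @property
    def is_hom_ref(self) -> bool:
        return self.gt == (0, 0)

    @property
    def is_het(self) -> bool:
        return self.n_alt_alleles == 1

    @property
    def is_hom_alt(self) -> bool:
        return self.gt is not None and self.gt[0] == 1 and self.gt[1] == 1


@dataclass(frozen=True)
class TrioPedigree:
    """Proband/father/mother sample mapping for one family."""

    family_id: str
    proband_id: str
    father_id: str
    mother_id: str
    proband_sex: Sex = Sex.UNKNOWN
    affected: bool = True

    def __post_init__(self) -> None:
        ids = {self.proband_id, self.father_id, self.mother_id}
        if len(ids) != 3:
            raise ValueError(
                f"trio {self.family_id} requires three distinct sample ids, got {ids}"
            )

    @property
    def samples(self) -> tuple[str, str, str]:
        return (self.proband_id, self.father_id, self.mother_id)


def normalize_symbol(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass(frozen=True)
class GenePanel:
    """A named set of HGNC gene symbols (uppercase, deduplicated)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"panel {self.name!r} is empty")

    @classmethod
    def from_symbols(cls, name: str, symbols) -> "GenePanel":
        return cls(name=name, genes=frozenset(normalize_symbol(s) for s in symbols if s.strip()))

    def __contains__(self, gene: str) -> bool:
        return normalize_symbol(gene) in self.genes

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ExpressionMatrix:
    """Gene x cell-type expression levels (non-negative, finite).

    Backed by a pandas DataFrame with gene symbols as the index and cell-type
    labels as columns.
    """

    values: "object"  # pandas.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ValueError(f"duplicate gene rows: {dups}")
        arr = df.to_numpy(dtype=float)
        if not math.isfinite(arr.sum()) or not (arr >= 0).all():
            raise ValueError("expression values must be finite and non-negative")
        df.index = [normalize_symbol(g) for g in df.index]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class InheritanceCall:
    """Origin classification for one (variant, proband) pair."""

    origin: Origin
    quality_pass: bool
    notes: str = ""


@dataclass(frozen=True)
class KinshipEstimate:
    """Robust within-pair kinship coefficient estimate.

    Expected values: ~0.25 for parent-offspring (with IBS0 near zero),
    ~0 for unrelated pairs, 0.5 for duplicates / monozygotic twins.
    """

    pair: tuple[str, str]
    kinship: float
    ibs0_rate: float
    n_sites: int

    def __post_init__(self) -> None:
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene-set over-representation test."""

    term_id: str
    term_genes: int  # K: annotated genes in the set (within background)
    query_hits: int  # k: query genes in the set
    query_size: int  # n
    background_size: int  # N
    p: float
    q: float = float("nan")
    overlap_genes: frozenset[str] = field(default_factory=frozenset)

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.p) if self.p > 0 else math.inf


@dataclass(frozen=True)
class CandidateGene:
    """A de novo gene scored by the pathway x expression intersection."""

    gene: str
    in_top_pathways: bool
    high_in_abc_or_plasma: bool
    prior_sle_gene: bool
    de_novo: bool
    n_pathway_clusters: int = 0

    @property
    def is_candidate(self) -> bool:
        return self.in_top_pathways and self.high_in_abc_or_plasma
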