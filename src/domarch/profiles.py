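"""Domain-hit parsing, filtering, and CDCP profile classification.

A CDCP (Competence-domain-containing protein) is any protein with a filtered
hit to the Pfam *Competence* domain (PF03772). Each protein is classified by
the combination of *DUF4131* (PF13567), *Competence*, and *Lactamase_B*
(PF00753) it carries — C, DC, CL, DCL — with any additional co-occurring
domain folding the protein into OTHER. A strain with no CDCP is NC; if its
genomic DNA nevertheless carries a passing nucleotide-level Competence match
the strain is flagged as harbouring a CDCP-like fragment ("genomic rescue").

Input dialects
--------------
Domain hits use the HMMER3 ``--domtblout`` column layout in the hmmsearch
orientation (query = profile HMM, target = protein): the independent e-value
("i-Evalue") is the filtered score and model coverage is
``(hmm_to - hmm_from + 1) / qlen``. Protein names follow the convention
``<proteome_id>|<protein_id>`` so every hit is attributable to a strain.
Nucleotide hits use BLAST ``-outfmt "6 qseqid sseqid pident length evalue
qcovs"``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "COMPETENCE",
    "DUF4131",
    "LACTAMASE_B",
    "CORE_DOMAINS",
    "STATES",
    "DomainHit",
    "ProteinProfile",
    "NucleotideHit",
    "StrainState",
    "parse_domtblout",
    "parse_blast_tab",
    "read_metadata",
    "filter_domain_hits",
    "build_profiles",
    "classify_protein",
    "rescue_filter",
    "strain_state",
    "strain_state_table",
    "states_to_frame",
    "frame_to_states",
    "census_report",
]

COMPETENCE = "PF03772"
DUF4131 = "PF13567"
LACTAMASE_B = "PF00753"
CORE_DOMAINS = frozenset({COMPETENCE, DUF4131, LACTAMASE_B})

#: Six-way strain-state vocabulary, in the fixed tie-break order.
STATES = ("NC", "C", "DC", "CL", "DCL", "OTHER")


@dataclass(frozen=True)
class DomainHit:
    """One protein-vs-domain-model match from a domtblout row."""

    protein_id: str
    proteome_id: str
    domain_accession: str
    domain_name: str
    evalue: float
    model_start: int
    model_end: int
    model_length: int
    env_start: int
    env_end: int
    protein_length: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.model_start <= self.model_end <= self.model_length):
            raise ValueError(
                f"bad model span {self.model_start}..{self.model_end}"
                f"/{self.model_length} for {self.protein_id}"
            )
        if self.evalue < 0:
            raise ValueError("negative e-value")
        if self.env_start > self.env_end:
            raise ValueError("env_start > env_end")

    @property
    def model_coverage(self) -> float:
        return (self.model_end - self.model_start + 1) / self.model_length


@dataclass(frozen=True)
class ProteinProfile:
    """Ordered (by envelope start) domain content of one protein."""

    protein_id: str
    proteome_id: str
    domains: Tuple[str, ...]
    is_cdcp: bool
    length: int = 0

    def __post_init__(self) -> None:
        if self.is_cdcp != (COMPETENCE in self.domains):
            raise ValueError("is_cdcp inconsistent with domain content")


@dataclass(frozen=True)
class NucleotideHit:
    """A blastn match of a Competence-domain subsequence against a genome."""

    query_id: str
    subject_genome_id: str
    evalue: float
    query_coverage: float
    identity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.query_coverage <= 1.0):
            raise ValueError("query_coverage outside [0, 1]")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity outside [0, 1]")


@dataclass(frozen=True)
class StrainState:
    """Per-strain six-way domain-profile state."""

    strain_id: str
    species: str
    state: str
    cdcp_count: int = 0
    genomic_fragment: bool = False
    # D/L content of the classifying CDCP; lets an OTHER strain be reduced to
    # one of the five core states for ancestral-state reconstruction.
    has_duf4131: bool = False
    has_lactamase_b: bool = False

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.state != "NC" and self.cdcp_count < 1:
            raise ValueError("non-NC state requires cdcp_count >= 1")
        if self.genomic_fragment and self.state != "NC":
            raise ValueError("genomic_fragment only applies to NC strains")


# ---------------------------------------------------------------------------
# parsing


def _split_protein_name(name: str) -> Tuple[str, str]:
    if "|" in name:
        proteome, _, protein = name.partition("|")
        return name, proteome
    return name, ""


def parse_domtblout(source) -> List[DomainHit]:
    """Parse a HMMER3 domtblout table (hmmsearch orientation).

    *source* is a path or an open text handle. Comment lines (``#``) and blank
    lines are skipped; a malformed row raises ``ValueError`` naming its line
    number.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    hits: List[DomainHit] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 22:
            raise ValueError(f"line {lineno}: expected >=22 columns, got {len(cols)}")
        try:
            protein_id, proteome_id = _split_protein_name(cols[0])
            accession = cols[4].split(".")[0]
            hit = DomainHit(
                protein_id=protein_id,
                proteome_id=proteome_id,
                domain_accession=accession,
                domain_name=cols[3],
                evalue=float(cols[12]),
                model_start=int(cols[15]),
                model_end=int(cols[16]),
                model_length=int(cols[5]),
                env_start=int(cols[19]),
                env_end=int(cols[20]),
                protein_length=int(cols[2]),
            )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
        hits.append(hit)
    return hits


def parse_blast_tab(source) -> List[NucleotideHit]:
    """Parse BLAST ``-outfmt "6 qseqid sseqid pident length evalue qcovs"``."""
    names = ["qseqid", "sseqid", "pident", "length", "evalue", "qcovs"]
    df = pd.read_csv(source, sep="\t", names=names, comment="#")
    if df.empty:
        return []
    hits = []
    for row in df.itertuples(index=False):
        hits.append(
            NucleotideHit(
                query_id=str(row.qseqid),
                subject_genome_id=str(row.sseqid),
                evalue=float(row.evalue),
                query_coverage=float(row.qcovs) / 100.0,
                identity=float(row.pident) / 100.0,
            )
        )
    return hits


def read_metadata(source) -> pd.DataFrame:
    """Read the strain metadata TSV (strain_id, species, taxon)."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    required = {"strain_id", "species", "taxon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# filtering and classification


def filter_domain_hits(
    hits: Sequence[DomainHit],
    evalue_max: float = 1e-5,
    model_coverage_min: float = 0.70,
) -> List[DomainHit]:
    """Drop hits with e-value above *evalue_max* or model coverage below
    *model_coverage_min*; both boundaries are inclusive keeps. Input order is
    preserved and the input list is not modified."""
    return [
        h
        for h in hits
        if h.evalue <= evalue_max and h.model_coverage >= model_coverage_min
    ]


def build_profiles(hits: Sequence[DomainHit]) -> List[ProteinProfile]:
    """Group filtered hits into per-protein domain profiles.

    Domains are ordered along the protein by envelope start; multiple hits of
    the same domain are all retained (multiplicity collapses only at state
    assignment).
    """
    by_protein: Dict[str, List[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    profiles = []
    for protein_id, group in by_protein.items():
        ordered = sorted(group, key=lambda h: (h.env_start, h.env_end))
        domains = tuple(h.domain_accession for h in ordered)
        profiles.append(
            ProteinProfile(
                protein_id=protein_id,
                proteome_id=group[0].proteome_id,
                domains=domains,
                is_cdcp=COMPETENCE in domains,
                length=max(h.protein_length for h in group),
            )
        )
    return profiles


def classify_protein(profile: ProteinProfile) -> Optional[str]:
    """Six-way state of one protein: C / DC / CL / DCL / OTHER, or ``None``
    if the protein carries no Competence domain (not a CDCP).

    Any filtered domain outside the {Competence, DUF4131, Lactamase_B} trio
    forces OTHER, regardless of which core domains co-occur.
    """
    present = set(profile.domains)
    if COMPETENCE not in present:
        return None
    if present - CORE_DOMAINS:
        return "OTHER"
    has_d = DUF4131 in present
    has_l = LACTAMASE_B in present
    return {(False, False): "C", (True, False): "DC",
            (False, True): "CL", (True, True): "DCL"}[(has_d, has_l)]


def rescue_filter(
    hit: NucleotideHit,
    evalue_max: float = 1e-5,
    qcov_min: float = 0.30,
    identity_min: float = 0.60,
) -> bool:
    """blastn genomic-rescue thresholds; all three boundaries inclusive."""
    return (
        hit.evalue <= evalue_max
        and hit.query_coverage >= qcov_min
        and hit.identity >= identity_min
    )


def strain_state(
    proteins: Sequence[ProteinProfile],
    nucleotide_hits: Sequence[NucleotideHit] = (),
    strain_id: Optional[str] = None,
    species: str = "",
) -> StrainState:
    """Derive the strain-level state from one strain's protein profiles.

    With at least one CDCP, the longest CDCP defines the state (ties broken by
    lexicographically smallest protein id). With none, the strain is NC, and
    ``genomic_fragment`` is set when any nucleotide hit passes the rescue
    filter.
    """
    if proteins:
        proteomes = {p.proteome_id for p in proteins}
        if len(proteomes) > 1:
            raise ValueError(f"proteins from multiple proteomes: {sorted(proteomes)}")
        sid = strain_id or proteins[0].proteome_id
    elif strain_id is not None:
        sid = strain_id
    else:
        raise ValueError("empty protein list and no strain_id given")

    cdcps = [p for p in proteins if p.is_cdcp]
    if cdcps:
        best = min(cdcps, key=lambda p: (-p.length, p.protein_id))
        present = set(best.domains)
        return StrainState(
            strain_id=sid,
            species=species,
            state=classify_protein(best),
            cdcp_count=len(cdcps),
            has_duf4131=DUF4131 in present,
            has_lactamase_b=LACTAMASE_B in present,
        )
    rescued = any(rescue_filter(h) for h in nucleotide_hits)
    return StrainState(
        strain_id=sid, species=species, state="NC", cdcp_count=0,
        genomic_fragment=rescued,
    )


def strain_state_table(
    profiles: Sequence[ProteinProfile],
    nucleotide_hits: Sequence[NucleotideHit],
    metadata: pd.DataFrame,
) -> List[StrainState]:
    """States for every strain listed in *metadata*.

    Strains without any protein profile are NC; nucleotide hits are matched to
    strains by their subject genome id.
    """
    prot_by_strain: Dict[str, List[ProteinProfile]] = {}
    for p in profiles:
        prot_by_strain.setdefault(p.proteome_id, []).append(p)
    nuc_by_strain: Dict[str, List[NucleotideHit]] = {}
    for h in nucleotide_hits:
        nuc_by_strain.setdefault(h.subject_genome_id, []).append(h)
    states = []
    for row in metadata.itertuples(index=False):
        states.append(
            strain_state(
                prot_by_strain.get(row.strain_id, []),
                nuc_by_strain.get(row.strain_id, []),
                strain_id=row.strain_id,
                species=row.species,
            )
        )
    return states


def states_to_frame(states: Sequence[StrainState]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strain_id": [s.strain_id for s in states],
            "species": [s.species for s in states],
            "state": [s.state for s in states],
            "cdcp_count": [s.cdcp_count for s in states],
            "genomic_fragment": [s.genomic_fragment for s in states],
            "has_duf4131": [s.has_duf4131 for s in states],
            "has_lactamase_b": [s.has_lactamase_b for s in states],
        }
    )


def frame_to_states(df: pd.DataFrame) -> List[StrainState]:
    def _bool(x) -> bool:
        return str(x).strip().lower() in {"true", "1"}

    return [
        StrainState(
            strain_id=str(r.strain_id),
            species=str(r.species),
            state=str(r.state),
            cdcp_count=int(r.cdcp_count),
            genomic_fragment=_bool(r.genomic_fragment),
            has_duf4131=_bool(getattr(r, "has_duf4131", False)),
            has_lactamase_b=_bool(getattr(r, "has_lactamase_b", False)),
        )
        for r in df.itertuples(index=False)
    ]


def _round_half_up(x: float, ndigits: int) -> float:
    import math

    scale = 10**ndigits
    return math.floor(x * scale + 0.5) / scale


def census_report(
    states: Sequence[StrainState], profiles: Sequence[ProteinProfile]
) -> Dict[str, float]:
    """Corpus-level summary: CDCP presence among proteomes and genomes, and
    DUF4131/Lactamase_B occurrence among CDCPs.

    Percentages are rounded half-up for presentation: presence percentages to
    integers, per-domain occurrence percentages to one decimal.
    """
    n_proteomes = len(states)
    n_cdcp_proteomes = sum(1 for s in states if s.state != "NC")
    n_rescued = sum(1 for s in states if s.state == "NC" and s.genomic_fragment)
    n_residual = n_proteomes - n_cdcp_proteomes - n_rescued
    cdcps = [p for p in profiles if p.is_cdcp]
    n_cdcps = len(cdcps)
    n_duf = sum(1 for p in cdcps if DUF4131 in p.domains)
    n_lact = sum(1 for p in cdcps if LACTAMASE_B in p.domains)
    return {
        "n_proteomes": n_proteomes,
        "n_cdcp_proteomes": n_cdcp_proteomes,
        "n_genomic_rescues": n_rescued,
        "n_residual_strains": n_residual,
        "n_cdcps": n_cdcps,
        "n_duf4131_occurrences": n_duf,
        "n_lactamase_b_occurrences": n_lact,
        "pct_proteomes_with_cdcp": _round_half_up(100.0 * n_cdcp_proteomes / n_proteomes, 0),
        "pct_genomes_with_cdcp_or_fragment": _round_half_up(
            100.0 * (n_cdcp_proteomes + n_rescued) / n_proteomes, 0
        ),
        "pct_cdcps_with_duf4131": _round_half_up(100.0 * n_duf / n_cdcps, 1),
        "pct_cdcps_with_lactamase_b": _round_half_up(100.0 * n_lact / n_cdcps, 1),
    }
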