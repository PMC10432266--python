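"""Discovery and classification of regulatory loci in linear plasmid-like prophages.

Linear plasmid-like phages (the N15/VP882 family) carry a protelomerase gene
(*telN*) and a replication-initiator gene (*repA*) as hallmarks.  The short
stretch of DNA between a convergently oriented telN/repA pair is where these
phages encode their lysis-control machinery (the cI repressor and, in some
phages, a transcription-factor/small-ORF induction module).  This module
implements the neighbourhood arithmetic used to mine such loci from annotated
contigs and homology-hit tables:

* convergent-pair discovery with a gap cap,
* extraction of the intervening nucleotides,
* identity / coverage / e-value filtering of homology hits,
* flanking-window extraction around an anchor gene,
* classification of a transcription-factor gene's genomic context, and
* a parB-anchored contig search (capsid-supported).

All coordinates are 1-based and inclusive, matching GFF3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GeneFeature",
    "AnnotatedContig",
    "HomologyHit",
    "RegulatoryLocus",
    "MalformedAnnotationError",
    "find_convergent_pairs",
    "extract_intervening",
    "filter_homology_hits",
    "window_extract",
    "classify_context",
    "parb_anchor_search",
]

#: Controlled vocabulary for gene labels used by the mining arm.
GENE_LABELS = frozenset(
    {"telN", "repA", "parB", "capsid", "terminase", "portal", "tf", "cI", "smORF", "other"}
)


class MalformedAnnotationError(ValueError):
    """A feature is missing the strand or coordinates the search needs."""


@dataclass(frozen=True)
class GeneFeature:
    """A strand-aware gene interval on a contig (1-based, inclusive)."""

    contig_id: str
    start: int
    end: int
    strand: str
    label: str
    source: str = "annotation"
    attrs: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise MalformedAnnotationError(
                f"feature {self.label}@{self.contig_id}:{self.start}-{self.end} "
                f"has invalid strand {self.strand!r}"
            )
        if not (1 <= self.start <= self.end):
            raise MalformedAnnotationError(
                f"feature {self.label}@{self.contig_id} has invalid coordinates "
                f"{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def gap_to(self, other: "GeneFeature") -> int:
        """Nucleotides strictly between two gene bodies (0 when they touch/overlap)."""
        return max(0, other.start - self.end - 1, self.start - other.end - 1)


@dataclass
class AnnotatedContig:
    """A contig with its features; ``sequence`` is optional."""

    id: str
    length: int
    features: list[GeneFeature] = field(default_factory=list)
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"contig {self.id}: sequence length {len(self.sequence)} != declared "
                f"length {self.length}"
            )
        for f in self.features:
            if f.end > self.length:
                raise MalformedAnnotationError(
                    f"feature {f.label}@{self.id}:{f.start}-{f.end} exceeds contig "
                    f"length {self.length}"
                )

    def features_with_label(self, label: str) -> list[GeneFeature]:
        return [f for f in self.features if f.label == label]


@dataclass(frozen=True)
class HomologyHit:
    """One row of a homology search (BLAST-style) against a contig."""

    query_id: str
    subject_contig: str
    percent_identity: float
    query_coverage: float
    evalue: float
    subject_start: int
    subject_end: int
    subject_strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.percent_identity <= 100:
            raise ValueError(f"percent_identity out of range: {self.percent_identity}")
        if not 0 <= self.query_coverage <= 100:
            raise ValueError(f"query_coverage out of range: {self.query_coverage}")
        if self.evalue < 0:
            raise ValueError(f"negative e-value: {self.evalue}")
        if self.subject_start > self.subject_end:
            raise ValueError("subject_start must be <= subject_end")


#: Genomic-context labels for transcription-factor homologues.
CONTEXT_LABELS = ("repA_telN", "parB_proximal", "terminase_portal_proximal", "heterogeneous")


@dataclass(frozen=True)
class RegulatoryLocus:
    """A validated convergent telN-repA locus with its intervening gap."""

    contig_id: str
    telN: GeneFeature
    repA: GeneFeature
    gap_bp: int
    intervening_sequence: str = ""
    convergent: bool = True
    context: str = "repA_telN"

    @property
    def upstream(self) -> GeneFeature:
        """The + strand (leftmost) gene of the convergent pair."""
        return self.telN if self.telN.start <= self.repA.start else self.repA

    @property
    def downstream(self) -> GeneFeature:
        return self.repA if self.telN.start <= self.repA.start else self.telN


def _is_convergent(left: GeneFeature, right: GeneFeature) -> bool:
    # 3' ends face each other: the + strand gene must lie upstream (left) of
    # the - strand gene.  Same-strand (tandem) and divergent pairs fail.
    return left.strand == "+" and right.strand == "-"


def find_convergent_pairs(
    contig: AnnotatedContig,
    label_a: str = "telN",
    label_b: str = "repA",
    max_sep_bp: int = 10_000,
) -> list[RegulatoryLocus]:
    """Return every convergent ``label_a``/``label_b`` pair within ``max_sep_bp``.

    A pair qualifies when the two genes are on opposite strands with their 3'
    ends pointing toward each other and the gap between the facing gene ends
    (``downstream.start - upstream.end - 1``, floored at 0 for overlapping
    genes) is at most ``max_sep_bp`` (inclusive).  Loci are ordered by the
    coordinate of the leftmost gene.
    """
    if max_sep_bp <= 0:
        raise ValueError("max_sep_bp must be positive")
    a_feats = contig.features_with_label(label_a)
    b_feats = contig.features_with_label(label_b)
    loci: list[RegulatoryLocus] = []
    for fa in a_feats:
        for fb in b_feats:
            left, right = (fa, fb) if fa.start <= fb.start else (fb, fa)
            if not _is_convergent(left, right):
                continue
            gap = max(0, right.start - left.end - 1)
            if gap > max_sep_bp:
                continue
            loci.append(
                RegulatoryLocus(contig_id=contig.id, telN=fa, repA=fb, gap_bp=gap)
            )
    loci.sort(key=lambda l: (l.upstream.start, l.downstream.start))
    return loci


class MissingSequenceError(ValueError):
    """The contig has no nucleotide sequence to extract from."""


def extract_intervening(locus: RegulatoryLocus, contig: AnnotatedContig) -> str:
    """Forward-strand nucleotides strictly between the two gene bodies.

    Empty when the genes abut or overlap; the length always equals
    ``locus.gap_bp``.
    """
    if contig.sequence is None:
        raise MissingSequenceError(f"contig {contig.id} carries no sequence")
    up, down = locus.upstream, locus.downstream
    if down.start <= up.end + 1:
        return ""
    # 1-based inclusive genes at ...-up.end and down.start-...: the gap is
    # bases up.end+1 .. down.start-1, i.e. 0-based slice [up.end, down.start-1).
    return contig.sequence[up.end : down.start - 1]


def filter_homology_hits(
    hits: Iterable[HomologyHit],
    min_identity: float,
    min_coverage: float,
    max_evalue: float,
) -> list[HomologyHit]:
    """Keep hits passing all three thresholds (inclusive comparisons).

    The convention is fixed as identity >= ``min_identity``, coverage >=
    ``min_coverage`` and e-value <= ``max_evalue``.
    """
    if min_identity < 0 or min_coverage < 0 or max_evalue < 0:
        raise ValueError("thresholds must be non-negative")
    return [
        h
        for h in hits
        if h.percent_identity >= min_identity
        and h.query_coverage >= min_coverage
        and h.evalue <= max_evalue
    ]


def window_extract(
    contig: AnnotatedContig, anchor: GeneFeature, flank_bp: int = 50_000
) -> AnnotatedContig:
    """Sub-contig spanning ``flank_bp`` on each side of ``anchor``, clipped.

    Features are re-coordinated to the window; features straddling a window
    boundary are truncated and flagged with ``attrs['truncated'] = 'true'``.
    """
    if anchor not in contig.features:
        raise LookupError(
            f"anchor {anchor.label}@{anchor.start}-{anchor.end} is not a feature of "
            f"contig {contig.id}"
        )
    win_start = max(1, anchor.start - flank_bp)
    win_end = min(contig.length, anchor.end + flank_bp)
    offset = win_start - 1
    new_features: list[GeneFeature] = []
    for f in contig.features:
        if f.end < win_start or f.start > win_end:
            continue
        truncated = f.start < win_start or f.end > win_end
        ns, ne = max(f.start, win_start) - offset, min(f.end, win_end) - offset
        attrs = dict(f.attrs)
        if truncated:
            attrs["truncated"] = "true"
        new_features.append(replace(f, start=ns, end=ne, attrs=attrs))
    seq = None
    if contig.sequence is not None:
        seq = contig.sequence[win_start - 1 : win_end]
    return AnnotatedContig(
        id=f"{contig.id}:{win_start}-{win_end}",
        length=win_end - win_start + 1,
        features=new_features,
        sequence=seq,
    )


def classify_context(
    contig: AnnotatedContig,
    anchor: GeneFeature,
    max_sep_bp: int = 10_000,
    pair_slop_bp: int = 1_000,
    parb_window_bp: int = 5_000,
    terminase_window_bp: int = 10_000,
) -> str:
    """Genomic-context label for a transcription-factor homologue.

    Precedence (fixed): ``repA_telN`` if the anchor overlaps the outer span of
    a convergent telN-repA pair padded by ``pair_slop_bp``; else
    ``parB_proximal`` if a parB gene lies within ``parb_window_bp`` of the
    anchor boundaries; else ``terminase_portal_proximal`` if a terminase or
    portal gene lies within ``terminase_window_bp``; else ``heterogeneous``.
    """
    for locus in find_convergent_pairs(contig, "telN", "repA", max_sep_bp):
        lo = min(locus.telN.start, locus.repA.start) - pair_slop_bp
        hi = max(locus.telN.end, locus.repA.end) + pair_slop_bp
        if anchor.start <= hi and anchor.end >= lo:
            return "repA_telN"
    if any(anchor.gap_to(f) <= parb_window_bp for f in contig.features_with_label("parB")):
        return "parB_proximal"
    near = [
        f
        for f in contig.features
        if f.label in ("terminase", "portal") and anchor.gap_to(f) <= terminase_window_bp
    ]
    if near:
        return "terminase_portal_proximal"
    return "heterogeneous"


def parb_anchor_search(
    contigs: Mapping[str, AnnotatedContig] | Sequence[AnnotatedContig],
    parb_hits: Iterable[HomologyHit],
    capsid_hits: Iterable[HomologyHit],
    tf_features: Iterable[GeneFeature],
    capsid_min_identity: float = 25.0,
    capsid_min_coverage: float = 70.0,
    parb_full_length_coverage: float = 90.0,
    tf_window_bp: int = 10_000,
) -> list[str]:
    """Contigs carrying a capsid-supported, TF-adjacent full-length parB locus.

    A contig qualifies when (i) it has a capsid homology hit passing the
    identity/coverage filter, (ii) it has a parB hit covering at least
    ``parb_full_length_coverage`` percent of the parB query (taken as
    "full-length"), and (iii) at least one predicted transcription-factor
    feature lies within ``tf_window_bp`` of that parB hit's boundaries.
    Returns sorted contig ids; empty inputs yield an empty list.
    """
    if isinstance(contigs, Mapping):
        contig_ids = set(contigs)
    else:
        contig_ids = {c.id for c in contigs}
    good_capsid = {
        h.subject_contig
        for h in filter_homology_hits(
            capsid_hits, capsid_min_identity, capsid_min_coverage, float("inf")
        )
    }
    full_parb: dict[str, list[HomologyHit]] = {}
    for h in parb_hits:
        if h.query_coverage >= parb_full_length_coverage:
            full_parb.setdefault(h.subject_contig, []).append(h)
    tfs_by_contig: dict[str, list[GeneFeature]] = {}
    for f in tf_features:
        tfs_by_contig.setdefault(f.contig_id, []).append(f)

    out = []
    for cid in sorted(contig_ids & good_capsid & set(full_parb)):
        for parb in full_parb[cid]:
            for tf in tfs_by_contig.get(cid, []):
                gap = max(0, tf.start - parb.subject_end - 1, parb.subject_start - tf.end - 1)
                if gap <= tf_window_bp:
                    out.append(cid)
                    break
            else:
                continue
            break
    return out
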