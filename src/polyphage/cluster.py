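"""Pairwise identity, greedy identity/coverage clustering, and repressor calls.

The clustering reproduces the cd-hit-est-style semantics used to group phage
locus sequences: sequences are ranked by length, the longest unassigned
sequence seeds a cluster, and a sequence joins a seed when the two share at
least ``identity_threshold`` identity over at least ``coverage_short`` of the
shorter sequence's length.  No k-mer prefilter is used: every comparison is a
full global alignment, trading speed for small-scale exactness.

Percent identity is reported with the shorter sequence's length as the
denominator (the clustering tool's convention); this is a documented choice,
since "percent identity" is otherwise ambiguous.

The module also implements the two ways of calling a phage cI repressor
autoproteolytic: ingestion of a conserved-domain feature table that marks
catalytic-site residues (primary), and a lower-confidence sequence heuristic
looking for an S24-peptidase-like Ser-Lys catalytic dyad downstream of an
Ala-Gly / Cys-Gly cleavage-site motif.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align

__all__ = [
    "SequenceRecord",
    "ClusterParams",
    "AlignmentScoring",
    "RepressorCall",
    "pairwise_identity",
    "align_pair",
    "greedy_cluster",
    "dereplicate_exact",
    "call_autoproteolytic",
    "DyadConfig",
]

_NUC = set("ACGTUNRYSWKMBDHV")
_PROT = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str
    alphabet: str = "nucleotide"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"sequence {self.id} is empty")
        allowed = _NUC if self.alphabet == "nucleotide" else _PROT
        bad = set(self.sequence.upper()) - allowed
        if bad:
            raise ValueError(
                f"sequence {self.id} has characters outside the {self.alphabet} "
                f"alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ClusterParams:
    """Identity threshold and shorter-sequence coverage, both fractions in (0, 1]."""

    identity_threshold: float = 0.8
    coverage_short: float = 0.95

    def __post_init__(self) -> None:
        for name, v in (("identity_threshold", self.identity_threshold),
                        ("coverage_short", self.coverage_short)):
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class AlignmentScoring:
    """Global-alignment scoring; defaults favour mismatches over gaps."""

    match: float = 1.0
    mismatch: float = 0.0
    gap_open: float = -5.0
    gap_extend: float = -0.5

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = self.match
        a.mismatch_score = self.mismatch
        a.open_gap_score = self.gap_open
        a.extend_gap_score = self.gap_extend
        return a


def align_pair(
    a: SequenceRecord, b: SequenceRecord, scoring: AlignmentScoring | None = None
) -> tuple[int, int]:
    """(identical aligned positions, aligned residue columns) for a global alignment."""
    if a.alphabet != b.alphabet:
        raise ValueError(f"alphabet mismatch: {a.id} is {a.alphabet}, {b.id} is {b.alphabet}")
    scoring = scoring or AlignmentScoring()
    aln = scoring.aligner().align(a.sequence.upper(), b.sequence.upper())[0]
    identical = 0
    aligned_cols = 0
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        aligned_cols += e1 - s1
        for i, j in zip(range(s1, e1), range(s2, e2)):
            if a.sequence[i].upper() == b.sequence[j].upper():
                identical += 1
    return identical, aligned_cols


def pairwise_identity(
    a: SequenceRecord, b: SequenceRecord, scoring: AlignmentScoring | None = None
) -> tuple[int, float]:
    """Global-alignment identity of two same-alphabet sequences.

    Returns ``(identical_positions, percent_identity)`` where the percentage
    denominator is the shorter sequence's length.
    """
    identical, _ = align_pair(a, b, scoring)
    denom = min(len(a), len(b))
    return identical, 100.0 * identical / denom


def _identity_and_coverage(
    a: SequenceRecord, b: SequenceRecord, scoring: AlignmentScoring
) -> tuple[float, float]:
    """(identity fraction over shorter length, aligned fraction of shorter)."""
    identical, aligned_cols = align_pair(a, b, scoring)
    short = min(len(a), len(b))
    return identical / short, aligned_cols / short


def greedy_cluster(
    seqs: Sequence[SequenceRecord],
    params: ClusterParams = ClusterParams(),
    assign: str = "best",
    scoring: AlignmentScoring | None = None,
) -> dict[str, str]:
    """Length-ranked greedy clustering; returns {sequence id: representative id}.

    Sequences are sorted by decreasing length (ties broken lexicographically by
    id).  The longest unassigned sequence seeds a cluster; each later sequence
    joins a qualifying seed — the highest-identity one when ``assign='best'``
    (default), or the longest (first in seed order) when ``assign='first'`` —
    or seeds a new cluster.  A sequence qualifies against a seed when identity
    >= ``identity_threshold`` computed over >= ``coverage_short`` of the
    shorter sequence's length.  Deterministic given ids and lengths.
    """
    if assign not in ("best", "first"):
        raise ValueError("assign must be 'best' or 'first'")
    scoring = scoring or AlignmentScoring()
    ordered = sorted(seqs, key=lambda s: (-len(s), s.id))
    seeds: list[SequenceRecord] = []
    assignment: dict[str, str] = {}
    for s in ordered:
        best_rep: str | None = None
        best_ident = -1.0
        for seed in seeds:
            ident, cov = _identity_and_coverage(s, seed, scoring)
            if cov >= params.coverage_short and ident >= params.identity_threshold:
                if assign == "first":
                    best_rep = seed.id
                    break
                if ident > best_ident:
                    best_ident, best_rep = ident, seed.id
        if best_rep is None:
            seeds.append(s)
            assignment[s.id] = s.id
        else:
            assignment[s.id] = best_rep
    return assignment


def dereplicate_exact(seqs: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Remove exact duplicates and exact substrings of longer retained sequences.

    Equivalent to clustering at identity 1.0 over 100% of the shorter sequence
    (with the identical-substring reading of that rule).  Representatives are
    returned in length-ranked order.
    """
    ordered = sorted(seqs, key=lambda s: (-len(s), s.id))
    kept: list[SequenceRecord] = []
    for s in ordered:
        su = s.sequence.upper()
        if any(su in k.sequence.upper() for k in kept):
            continue
        kept.append(s)
    return kept


# --- autoproteolysis calling -------------------------------------------------

@dataclass(frozen=True)
class DyadConfig:
    """Spacing windows (in residues) for the heuristic Ser-Lys dyad caller.

    Defaults bracket the canonical lambda cI geometry: cleavage between
    Ala111-Gly112, catalytic Ser149 (37 residues after the cleavage Ala) and
    catalytic Lys192 (43 residues after the serine).
    """

    cleavage_motifs: tuple[str, ...] = ("AG", "CG")
    ser_offset_min: int = 20
    ser_offset_max: int = 60
    lys_offset_min: int = 30
    lys_offset_max: int = 60
    min_cleavage_pos: int = 40  # cleavage site sits after the DNA-binding domain


@dataclass(frozen=True)
class RepressorCall:
    id: str
    autoproteolytic: bool
    evidence: str  # "feature_table" or "motif_heuristic"
    detail: str = ""


def _heuristic_dyad(seq: str, cfg: DyadConfig) -> str | None:
    s = seq.upper()
    for motif in cfg.cleavage_motifs:
        for m in re.finditer(re.escape(motif), s):
            i = m.start()
            if i < cfg.min_cleavage_pos:
                continue
            for j in range(i + cfg.ser_offset_min, min(i + cfg.ser_offset_max, len(s) - 1) + 1):
                if j >= len(s) or s[j] != "S":
                    continue
                lo = j + cfg.lys_offset_min
                hi = min(j + cfg.lys_offset_max, len(s) - 1)
                if "K" in s[lo : hi + 1]:
                    return (
                        f"cleavage {motif} at {i + 1}, catalytic Ser at {j + 1}, "
                        f"Lys within {cfg.lys_offset_min}-{cfg.lys_offset_max} residues"
                    )
    return None


def call_autoproteolytic(
    protein_id: str,
    sequence: str | None = None,
    feature_rows: Iterable[Mapping[str, str]] | None = None,
    dyad_config: DyadConfig = DyadConfig(),
) -> RepressorCall:
    """Call a cI repressor autoproteolytic.

    Ingestion mode (primary): ``feature_rows`` are conserved-domain feature
    records with at least ``protein_id`` and ``feature_type`` keys; the call is
    true iff a row for this protein marks catalytic-site residues.

    Heuristic mode (lower confidence, used when no feature table is given): the
    call is true iff the sequence contains a cleavage-site motif (Ala-Gly or
    Cys-Gly) followed by a serine and a lysine at S24-peptidase-like spacings
    (see :class:`DyadConfig`).
    """
    if feature_rows is not None:
        rows = [r for r in feature_rows if r.get("protein_id") == protein_id]
        hit = [r for r in rows if "catalytic" in str(r.get("feature_type", "")).lower()]
        detail = hit[0].get("positions", "") if hit else "no catalytic-site feature"
        return RepressorCall(protein_id, bool(hit), "feature_table", str(detail))
    if sequence is not None:
        detail = _heuristic_dyad(sequence, dyad_config)
        return RepressorCall(
            protein_id, detail is not None, "motif_heuristic", detail or "no dyad motif found"
        )
    raise ValueError("either feature_rows or sequence must be provided")
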