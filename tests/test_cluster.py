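"""Alignment identity, greedy clustering vs a brute-force oracle, repressor calls."""

import numpy as np
import pytest

from polyphage.cluster import (
    ClusterParams,
    SequenceRecord,
    call_autoproteolytic,
    dereplicate_exact,
    greedy_cluster,
    pairwise_identity,
)
from polyphage.simulate import make_repressor_sequence, random_dna

# ---------------------------------------------------------------------------
# independent dynamic-programming oracle (affine-gap global alignment,
# match=1 / mismatch=0 / open=-5 / extend=-0.5, mirroring the library default)
# ---------------------------------------------------------------------------

_OPEN, _EXT = -5.0, -0.5
_NEG = float("-inf")


def _nw_oracle(a: str, b: str) -> tuple[int, int]:
    """(identical positions, aligned columns) of an optimal global alignment."""
    n, m = len(a), len(b)
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = _OPEN + (i - 1) * _EXT
    for j in range(1, m + 1):
        Y[0][j] = _OPEN + (j - 1) * _EXT
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = 1.0 if a[i - 1] == b[j - 1] else 0.0
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + _OPEN, X[i - 1][j] + _EXT, Y[i - 1][j] + _OPEN)
            Y[i][j] = max(M[i][j - 1] + _OPEN, X[i][j - 1] + _OPEN, Y[i][j - 1] + _EXT)
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda st: {"M": M, "X": X, "Y": Y}[st][i][j])
    identical = cols = 0
    while i > 0 or j > 0:
        if state == "M":
            s = 1.0 if a[i - 1] == b[j - 1] else 0.0
            cols += 1
            identical += int(a[i - 1] == b[j - 1])
            prev = M[i][j] - s
            i, j = i - 1, j - 1
            state = next(
                st for st in ("M", "X", "Y")
                if abs({"M": M, "X": X, "Y": Y}[st][i][j] - prev) < 1e-9
            ) if (i, j) != (0, 0) else "M"
        elif state == "X":
            v = X[i][j]
            if abs(M[i - 1][j] + _OPEN - v) < 1e-9:
                state = "M"
            elif abs(X[i - 1][j] + _EXT - v) < 1e-9:
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:
            v = Y[i][j]
            if abs(M[i][j - 1] + _OPEN - v) < 1e-9:
                state = "M"
            elif abs(Y[i][j - 1] + _EXT - v) < 1e-9:
                state = "Y"
            else:
                state = "X"
            j -= 1
    return identical, cols


def oracle_greedy(seqs, params: ClusterParams) -> dict[str, str]:
    """Brute-force greedy rule with all pairwise alignments from the oracle DP."""
    ordered = sorted(seqs, key=lambda s: (-len(s.sequence), s.id))
    reps: list[SequenceRecord] = []
    assign: dict[str, str] = {}
    for s in ordered:
        best, best_ident = None, -1.0
        for r in reps:
            identical, cols = _nw_oracle(s.sequence.upper(), r.sequence.upper())
            short = min(len(s.sequence), len(r.sequence))
            ident, cov = identical / short, cols / short
            if cov >= params.coverage_short and ident >= params.identity_threshold:
                if ident > best_ident:
                    best, best_ident = r.id, ident
        if best is None:
            reps.append(s)
            assign[s.id] = s.id
        else:
            assign[s.id] = best
    return assign


# ---------------------------------------------------------------------------
# pairwise identity
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("ACDE", "ACDE", (4, 100.0)),
        ("ACDE", "ACDF", (3, 75.0)),
    ],
)
def test_pairwise_identity_simple(a, b, expected):
    ra, rb = SequenceRecord("a", a, "protein"), SequenceRecord("b", b, "protein")
    assert pairwise_identity(ra, rb) == expected


def test_pairwise_identity_matches_dp_oracle():
    a, b = "MKTAYIAKQR", "MKTVYIPKQW"
    identical, cols = _nw_oracle(a, b)
    got_id, got_pct = pairwise_identity(
        SequenceRecord("a", a, "protein"), SequenceRecord("b", b, "protein")
    )
    assert got_id == identical == 7
    assert got_pct == pytest.approx(100.0 * identical / 10)


def test_pairwise_identity_alphabet_mismatch():
    with pytest.raises(ValueError, match="alphabet"):
        pairwise_identity(
            SequenceRecord("a", "ACGT", "nucleotide"),
            SequenceRecord("b", "ACDE", "protein"),
        )


# ---------------------------------------------------------------------------
# greedy clustering
# ---------------------------------------------------------------------------

def _family_set(rng, n_families=8, members=(4, 9), length=(50, 80), mut=0.05):
    """Sequence families: high within-family identity, unrelated across."""
    seqs = []
    k = 0
    while len(seqs) < 50:
        base = random_dna(int(rng.integers(*length)), 0.5, rng)
        fam = int(rng.integers(*members))
        for _ in range(fam):
            if len(seqs) >= 50:
                break
            s = list(base)
            for i in range(len(s)):
                if rng.uniform() < mut:
                    s[i] = "ACGT"[int(rng.integers(4))]
            # occasional 1-2 bp end trim keeps coverage near 1
            trim = int(rng.integers(0, 3))
            seqs.append(SequenceRecord(f"s{k:03d}", "".join(s[: len(s) - trim] or s)))
            k += 1
    return seqs


def test_identical_pair_forms_one_cluster():
    seqs = [SequenceRecord("a", "ACGTACGTAA"), SequenceRecord("b", "ACGTACGTAA")]
    assign = greedy_cluster(seqs)
    assert len(set(assign.values())) == 1


def test_unrelated_sequences_stay_apart(rng):
    seqs = [
        SequenceRecord("a", random_dna(300, 0.5, rng)),
        SequenceRecord("b", random_dna(300, 0.5, rng)),
    ]
    assign = greedy_cluster(seqs, ClusterParams(0.8, 0.95))
    assert assign == {"a": "a", "b": "b"}


def test_chain_clusters_with_longest_seed(rng):
    """B joins the A seed it matches; unrelated C seeds its own cluster."""
    base = random_dna(300, 0.5, rng)
    b = list(base[:290])
    for i in range(0, len(b), 12):  # ~8% substitutions -> identity ~0.92
        b[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[i]]
    seqs = [
        SequenceRecord("A", base),
        SequenceRecord("B", "".join(b)),
        SequenceRecord("C", random_dna(280, 0.5, rng)),
    ]
    assign = greedy_cluster(seqs, ClusterParams(0.8, 0.95))
    assert assign == {"A": "A", "B": "A", "C": "C"}
    assert assign == oracle_greedy(seqs, ClusterParams(0.8, 0.95))


def test_greedy_matches_bruteforce_oracle_on_families(rng):
    seqs = _family_set(rng)
    params = ClusterParams(0.8, 0.95)
    assert greedy_cluster(seqs, params) == oracle_greedy(seqs, params)


def test_cluster_idempotence(rng):
    seqs = _family_set(rng)
    assign = greedy_cluster(seqs)
    reps = [s for s in seqs if assign[s.id] == s.id]
    again = greedy_cluster(reps)
    assert all(v == k for k, v in again.items())


def test_threshold_monotonicity(rng):
    seqs = _family_set(rng)
    counts = []
    for thr in (0.95, 0.8, 0.6, 0.4):
        assign = greedy_cluster(seqs, ClusterParams(thr, 0.95))
        counts.append(len(set(assign.values())))
    assert counts == sorted(counts, reverse=True)


def test_empty_input():
    assert greedy_cluster([]) == {}


# ---------------------------------------------------------------------------
# dereplication
# ---------------------------------------------------------------------------

def test_dereplicate_duplicates_and_substrings():
    x = "ACGTACGTACGTACGT"
    seqs = [
        SequenceRecord("x1", x),
        SequenceRecord("x2", x),
        SequenceRecord("pfx", x[:8]),
        SequenceRecord("y", "TTTTGGGGCCCCAAAA"),
    ]
    kept = {s.id for s in dereplicate_exact(seqs)}
    assert kept == {"x1", "y"}


def test_dereplicate_never_removes_non_substrings(rng):
    seqs = [SequenceRecord(f"r{i}", random_dna(int(rng.integers(20, 60)), 0.5, rng)) for i in range(20)]
    seqs += [SequenceRecord(f"d{i}", seqs[i].sequence[: 10 + i]) for i in range(5)]
    kept = dereplicate_exact(seqs)
    kept_seqs = [s.sequence for s in kept]
    for s in seqs:
        if s.sequence not in kept_seqs:
            assert any(s.sequence in k for k in kept_seqs)


# ---------------------------------------------------------------------------
# autoproteolysis calls
# ---------------------------------------------------------------------------

def test_feature_table_mode():
    rows = [
        {"protein_id": "cI_72", "feature_type": "catalytic site", "positions": "S149,K192"},
        {"protein_id": "cI_N15", "feature_type": "DNA-binding domain", "positions": "1-60"},
    ]
    call = call_autoproteolytic("cI_72", feature_rows=rows)
    assert call.autoproteolytic and call.evidence == "feature_table"
    call2 = call_autoproteolytic("cI_N15", feature_rows=rows)
    assert not call2.autoproteolytic


def test_heuristic_mode_planted_and_destroyed_dyad():
    good = make_repressor_sequence(seed=5, autoproteolytic=True)
    bad = make_repressor_sequence(seed=5, autoproteolytic=False)
    assert call_autoproteolytic("good", sequence=good).autoproteolytic
    assert not call_autoproteolytic("bad", sequence=bad).autoproteolytic
    assert call_autoproteolytic("good", sequence=good).evidence == "motif_heuristic"


def test_call_requires_some_input():
    with pytest.raises(ValueError):
        call_autoproteolytic("x")
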