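"""Locus-mining behaviour: convergence geometry, gaps, filters, contexts."""

import pytest

from polyphage.mining import (
    AnnotatedContig,
    GeneFeature,
    HomologyHit,
    MalformedAnnotationError,
    classify_context,
    extract_intervening,
    filter_homology_hits,
    find_convergent_pairs,
    parb_anchor_search,
    window_extract,
)


@pytest.mark.parametrize(
    "strand_a,strand_b,start_b,expected_n,expected_gap",
    [
        ("+", "-", 5000, 1, 1999),  # convergent, facing 3' ends
        ("+", "+", 5000, 0, None),  # tandem
        ("-", "+", 5000, 0, None),  # divergent (3' ends point away)
        ("+", "-", 14000, 0, None),  # convergent but gap 10999 > cap
    ],
)
def test_convergent_pair_geometry(contig_factory, strand_a, strand_b, start_b, expected_n, expected_gap):
    contig = contig_factory(
        30_000,
        [("telN", strand_a, 1000, 3000), ("repA", strand_b, start_b, start_b + 2000)],
    )
    loci = find_convergent_pairs(contig, "telN", "repA", max_sep_bp=10_000)
    assert len(loci) == expected_n
    if expected_n:
        assert loci[0].gap_bp == expected_gap
        assert loci[0].convergent


def test_repA_upstream_orientation_also_counts(contig_factory):
    # repA(+) upstream of telN(-) is equally convergent
    contig = contig_factory(30_000, [("repA", "+", 1000, 3000), ("telN", "-", 5000, 7000)])
    loci = find_convergent_pairs(contig)
    assert len(loci) == 1 and loci[0].gap_bp == 1999


def test_overlapping_convergent_genes_have_zero_gap(contig_factory):
    contig = contig_factory(10_000, [("telN", "+", 1000, 3000), ("repA", "-", 2500, 4500)])
    (locus,) = find_convergent_pairs(contig)
    assert locus.gap_bp == 0
    contig.sequence = "A" * 10_000
    assert extract_intervening(locus, contig) == ""


def test_gap_cap_is_inclusive(contig_factory):
    contig = contig_factory(30_000, [("telN", "+", 1000, 2000), ("repA", "-", 12_001, 13_000)])
    (locus,) = find_convergent_pairs(contig, max_sep_bp=10_000)
    assert locus.gap_bp == 10_000


@pytest.mark.parametrize(
    "g1,g2,expected",
    [((1, 10), (16, 25), 5), ((1, 10), (11, 20), 0)],
)
def test_intervening_extraction(g1, g2, expected):
    seq = "ACGTACGTACNNNNNACGTACGTACGTACG"
    contig = AnnotatedContig(
        id="c",
        length=30,
        sequence=seq,
        features=[
            GeneFeature("c", g1[0], g1[1], "+", "telN"),
            GeneFeature("c", g2[0], g2[1], "-", "repA"),
        ],
    )
    (locus,) = find_convergent_pairs(contig, max_sep_bp=30)
    got = extract_intervening(locus, contig)
    assert len(got) == expected == locus.gap_bp
    if expected:
        assert got == seq[g1[1] : g2[0] - 1]


def test_intervening_length_always_equals_gap(contig_factory, rng):
    for _ in range(50):
        s1 = int(rng.integers(1, 100))
        e1 = s1 + int(rng.integers(10, 50))
        s2 = e1 + int(rng.integers(0, 60)) + 1
        e2 = s2 + int(rng.integers(10, 50))
        length = e2 + 10
        seq = "".join(rng.choice(list("ACGT"), size=length))
        contig = contig_factory(
            length, [("telN", "+", s1, e1), ("repA", "-", s2, e2)], seq=seq
        )
        for locus in find_convergent_pairs(contig, max_sep_bp=length):
            assert len(extract_intervening(locus, contig)) == locus.gap_bp


def _revcomp_contig(contig):
    comp = str.maketrans("ACGT", "TGCA")
    feats = [
        GeneFeature(
            contig_id=f.contig_id,
            start=contig.length - f.end + 1,
            end=contig.length - f.start + 1,
            strand="-" if f.strand == "+" else "+",
            label=f.label,
        )
        for f in contig.features
    ]
    seq = contig.sequence.translate(comp)[::-1] if contig.sequence else None
    return AnnotatedContig(id=contig.id, length=contig.length, features=feats, sequence=seq)


def test_strand_flip_symmetry(contig_factory, rng):
    """Reverse-complementing a contig leaves detected loci and gaps unchanged."""
    for _ in range(25):
        s1 = int(rng.integers(1, 2000))
        e1 = s1 + int(rng.integers(100, 1500))
        s2 = e1 + int(rng.integers(0, 12_000)) + 1
        e2 = s2 + int(rng.integers(100, 1500))
        strands = [("+", "-"), ("+", "+"), ("-", "+"), ("-", "-")][int(rng.integers(4))]
        contig = contig_factory(
            e2 + 100, [("telN", strands[0], s1, e1), ("repA", strands[1], s2, e2)]
        )
        fwd = find_convergent_pairs(contig)
        rev = find_convergent_pairs(_revcomp_contig(contig))
        assert [l.gap_bp for l in fwd] == [l.gap_bp for l in rev]


def test_malformed_feature_is_rejected():
    with pytest.raises(MalformedAnnotationError):
        GeneFeature("c", 10, 5, "+", "telN")
    with pytest.raises(MalformedAnnotationError):
        GeneFeature("c", 1, 5, ".", "telN")


@pytest.mark.parametrize(
    "ident,cov,evalue,kept",
    [
        (40.0, 75.0, 1e-5, True),
        (34.9, 90.0, 1e-20, False),
        (60.0, 69.9, 1e-20, False),
        (35.0, 70.0, 1e-3, True),  # thresholds are inclusive
    ],
)
def test_homology_hit_filter(ident, cov, evalue, kept):
    hit = HomologyHit("q", "s", ident, cov, evalue, 1, 100)
    out = filter_homology_hits([hit], min_identity=35, min_coverage=70, max_evalue=1e-3)
    assert (len(out) == 1) is kept


def test_homology_filter_rejects_negative_thresholds():
    with pytest.raises(ValueError):
        filter_homology_hits([], -1, 70, 1e-3)


def test_window_extract_clipping_and_truncation(contig_factory):
    contig = contig_factory(
        200_000,
        [
            ("tf", "+", 60_000, 61_000),
            ("parB", "+", 5_000, 15_000),  # straddles the left window edge
            ("capsid", "+", 150_000, 151_000),  # outside the window
        ],
    )
    anchor = contig.features[0]
    win = window_extract(contig, anchor, flank_bp=50_000)
    assert win.id == "ctg:10000-111000"
    assert win.length == 101_001
    labels = {f.label: f for f in win.features}
    assert "capsid" not in labels
    parb = labels["parB"]
    assert parb.start == 1 and parb.attrs.get("truncated") == "true"
    assert labels["tf"].start == 60_000 - 9_999


def test_window_extract_left_clip(contig_factory):
    contig = contig_factory(200_000, [("tf", "+", 1_000, 2_000)])
    win = window_extract(contig, contig.features[0], flank_bp=50_000)
    assert win.id == "ctg:1-52000" and win.length == 52_000


def test_window_extract_unknown_anchor(contig_factory):
    contig = contig_factory(10_000, [("tf", "+", 100, 200)])
    stranger = GeneFeature("ctg", 300, 400, "+", "tf")
    with pytest.raises(LookupError):
        window_extract(contig, stranger)


@pytest.mark.parametrize(
    "features,anchor_pos,expected",
    [
        # anchor inside a convergent telN/repA interval
        ([("telN", "+", 1000, 3000), ("repA", "-", 9000, 11_000)], (4000, 5000), "repA_telN"),
        # 3 kb from parB, no pair
        ([("parB", "+", 10_000, 11_000)], (5000, 6999), "parB_proximal"),
        # 12 kb from parB but 8 kb from a terminase
        ([("parB", "+", 20_000, 21_000), ("terminase", "+", 14_000, 15_000)], (1000, 5999), "terminase_portal_proximal"),
        # nothing nearby
        ([("parB", "+", 30_000, 31_000)], (1000, 2000), "heterogeneous"),
    ],
)
def test_context_classification(contig_factory, features, anchor_pos, expected):
    anchor = ("tf", "+", anchor_pos[0], anchor_pos[1])
    contig = contig_factory(40_000, features + [anchor])
    tf = contig.features_with_label("tf")[0]
    assert classify_context(contig, tf) == expected


def test_context_precedence_and_order_invariance(contig_factory, rng):
    """repA_telN wins over parB; labels don't depend on feature order."""
    features = [
        ("telN", "+", 1000, 3000),
        ("repA", "-", 9000, 11_000),
        ("parB", "+", 5500, 6500),
        ("tf", "+", 4000, 5000),
    ]
    contig = contig_factory(20_000, features)
    tf = contig.features_with_label("tf")[0]
    assert classify_context(contig, tf) == "repA_telN"
    for _ in range(5):
        perm = [features[i] for i in rng.permutation(len(features))]
        c2 = contig_factory(20_000, perm)
        tf2 = c2.features_with_label("tf")[0]
        assert classify_context(c2, tf2) == "repA_telN"


def _parb_inputs(tf_offset_bp, capsid_identity=30.0, parb_cov=95.0):
    contig = AnnotatedContig(id="c1", length=100_000)
    parb = HomologyHit("parB_query", "c1", 80.0, parb_cov, 1e-30, 40_000, 41_000)
    capsid = HomologyHit("capsid_query", "c1", capsid_identity, 80.0, 1e-10, 60_000, 61_000)
    tf = GeneFeature("c1", 41_001 + tf_offset_bp, 42_000 + tf_offset_bp, "+", "tf")
    return {"c1": contig}, [parb], [capsid], [tf]


@pytest.mark.parametrize(
    "tf_offset,capsid_identity,parb_cov,included",
    [
        (4_000, 30.0, 95.0, True),
        (12_000, 30.0, 95.0, False),  # TF too far from parB
        (4_000, 20.0, 95.0, False),  # capsid hit below 25% identity
        (4_000, 30.0, 80.0, False),  # parB not full-length
    ],
)
def test_parb_anchor_search(tf_offset, capsid_identity, parb_cov, included):
    contigs, parb, capsid, tfs = _parb_inputs(tf_offset, capsid_identity, parb_cov)
    got = parb_anchor_search(contigs, parb, capsid, tfs)
    assert got == (["c1"] if included else [])


def test_parb_anchor_search_empty_inputs():
    assert parb_anchor_search({}, [], [], []) == []
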