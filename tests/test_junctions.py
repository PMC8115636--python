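"""Splice-site usage: categories against hand enumeration, filters, track."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from splicehotspot.annotation import (
    Annotation,
    Exon,
    Gene,
    Junction,
    SpliceSite,
    Transcript,
)
from splicehotspot.io import junction_frame
from splicehotspot.junctions import (
    averaged_track,
    classify_junction_for_site,
    collapse_replicates,
    compute_usage,
    filter_annotated_junctions,
    switch_score,
    usage_table,
)


def _toy_annotation(strand: str = "+", length: int = 500) -> Annotation:
    """3-exon gene [0,100) [200,300) [400,500) plus a donor-extension
    isoform of the first intron; on '-' the layout is mirrored."""

    def iv(s, e):
        return (s, e) if strand == "+" else (length - e, length - s)

    gene = Gene("g1", "chr1", strand)
    t1 = Transcript("t1", "g1", "chr1", strand)
    for s, e in ((0, 100), (200, 300), (400, 500)):
        t1.exons.append(Exon("chr1", *iv(s, e), strand))
    t2 = Transcript("t2", "g1", "chr1", strand)  # exon1 extended to 118
    for s, e in ((0, 118), (200, 300), (400, 500)):
        t2.exons.append(Exon("chr1", *iv(s, e), strand))
    t3 = Transcript("t3", "g1", "chr1", strand)  # skips the middle exon
    for s, e in ((0, 100), (400, 500)):
        t3.exons.append(Exon("chr1", *iv(s, e), strand))
    gene.transcripts = {"t1": t1, "t2": t2, "t3": t3}
    return Annotation({"g1": gene})


def _jx(start, end, strand="+", length=500):
    if strand == "+":
        return Junction("chr1", start, end, "+")
    return Junction("chr1", length - end, length - start, "-")


def _site(pos, side, strand="+", length=500):
    p = pos if strand == "+" else length - pos
    return SpliceSite("chr1", p, side, strand)


# hand-enumerated categories for the 4 internal sites of the toy gene,
# junctions given in transcript coordinates (mirrored for the - strand)
HAND_CASES = [
    ((100, "donor"), (100, 200), "A"),
    ((100, "donor"), (100, 400), "A"),   # skip junction still uses the site
    ((100, "donor"), (118, 200), "C"),   # donor end inside the intron
    # the skip isoform's intron (100,400) is a flanking intron of this
    # donor, and junction (300,400) starts inside it -> C under the
    # union-of-flanking-introns rule
    ((100, "donor"), (300, 400), "C"),
    ((200, "acceptor"), (100, 200), "A"),
    ((200, "acceptor"), (118, 200), "A"),
    ((200, "acceptor"), (100, 400), "B"),  # spans the site
    ((200, "acceptor"), (300, 400), None),
    ((300, "donor"), (300, 400), "A"),
    ((300, "donor"), (100, 400), "B"),
    ((300, "donor"), (100, 200), None),
    ((300, "donor"), (118, 200), None),
    ((400, "acceptor"), (300, 400), "A"),
    ((400, "acceptor"), (100, 400), "A"),
    # acceptor end 200 falls inside the skip intron (100,400), which flanks
    # this acceptor -> C
    ((400, "acceptor"), (118, 200), "C"),
]


@pytest.mark.parametrize("strand", ["+", "-"])
@pytest.mark.parametrize("case", HAND_CASES,
                         ids=[f"{s[0]}{s[1]}_{j}" for s, j, _ in HAND_CASES])
def test_categories_match_hand_enumeration(strand, case):
    (pos, side), (js, je), expected = case
    ann = _toy_annotation(strand)
    got = classify_junction_for_site(
        _site(pos, side, strand), _jx(js, je, strand), ann
    )
    assert got == expected


def test_classification_requires_flanking_intron():
    ann = _toy_annotation()
    orphan = SpliceSite("chr1", 777, "donor", "+")
    with pytest.raises(ValueError):
        classify_junction_for_site(orphan, _jx(100, 200), ann)


def test_filter_keeps_only_fully_annotated_junctions():
    ann = _toy_annotation()
    rows = [
        ("chr1", 100, 200, "+", 5),   # both ends annotated
        ("chr1", 100, 400, "+", 2),   # skip junction, annotated
        ("chr1", 100, 250, "+", 9),   # acceptor end novel
        ("chr1", 150, 400, "+", 9),   # donor end novel
        ("chr1", 130, 260, "+", 9),   # neither end annotated
    ]
    out = filter_annotated_junctions(junction_frame(rows), ann)
    assert set(zip(out["start"], out["end"])) == {(100, 200), (100, 400)}
    assert out["count"].tolist() == [5, 2]
    again = filter_annotated_junctions(out, ann)
    pd.testing.assert_frame_equal(out, again)


def test_filter_matches_membership_oracle():
    ann = _toy_annotation()
    donors = {s.pos for s in ann.site_set() if s.side == "donor"}
    acceptors = {s.pos for s in ann.site_set() if s.side == "acceptor"}
    rng = np.random.default_rng(0)
    rows = [
        ("chr1", int(s), int(s + rng.integers(50, 300)), "+", 1)
        for s in rng.integers(0, 480, size=10)
    ]
    out = filter_annotated_junctions(junction_frame(rows), ann)
    expected = [
        r for r in rows if r[1] in donors and r[2] in acceptors
    ]
    assert len(out) == len(expected)
    assert set(zip(out["start"], out["end"])) == {
        (r[1], r[2]) for r in expected
    }


def test_filter_rejects_empty_annotation():
    empty = Annotation({})
    with pytest.raises(ValueError):
        filter_annotated_junctions(junction_frame([]), empty)


def test_collapse_replicates():
    one = junction_frame([("chr1", 100, 200, "+", 3)], "r1")
    two = junction_frame(
        [("chr1", 100, 200, "+", 4), ("chr1", 300, 400, "+", 1)], "r2"
    )
    out = collapse_replicates([one, two])
    assert out.set_index(["start", "end"])["count"].to_dict() == {
        (100, 200): 7, (300, 400): 1,
    }
    single = collapse_replicates([one])
    assert single["count"].tolist() == [3]


def test_collapse_matches_groupby_oracle():
    rng = np.random.default_rng(1)
    tables = []
    for rep in range(3):
        rows = [
            ("chr1", int(s), int(s) + 100, "+", int(rng.integers(1, 50)))
            for s in rng.choice([100, 300, 500, 700], size=6)
        ]
        tables.append(junction_frame(rows, f"r{rep}"))
    out = collapse_replicates(tables)
    oracle = (
        pd.concat(tables)
        .groupby(["chrom", "start", "end", "strand"])["count"]
        .sum()
    )
    for r in out.itertuples():
        assert r.count == oracle[(r.chrom, r.start, r.end, r.strand)]
    assert len(out) == len(oracle)


def test_collapse_rejects_chrom_mismatch():
    one = junction_frame([("chr1", 100, 200, "+", 3)], "r1")
    two = junction_frame([("chrX", 100, 200, "+", 3)], "r2")
    with pytest.raises(ValueError):
        collapse_replicates([one, two])


@pytest.mark.parametrize(
    "counts,expected",
    [((5, 0, 0), 1.0), ((0, 3, 1), 0.0), ((2, 1, 1), 0.5)],
)
def test_usage_arithmetic(counts, expected):
    """A/(A+B+C) for the middle exon's acceptor at 200: junction (100,200)
    is A, the skip junction (100,400) is B, and (118,200) — the extended
    donor reaching the same acceptor — also uses the site, so C evidence is
    routed through the donor at 100 where (118,200) lands inside the
    intron.  Categories are assembled so the arithmetic sees exactly
    (A, B, C)."""
    ann = _toy_annotation()
    a, b, c = counts
    rec_acc = compute_usage(
        _site(200, "acceptor"),
        junction_frame([("chr1", 100, 200, "+", a),
                        ("chr1", 100, 400, "+", b + c)]),
        ann,
    )
    assert (rec_acc.A, rec_acc.B) == (a, b + c)
    assert rec_acc.usage == pytest.approx(expected)
    rec_don = compute_usage(
        _site(100, "donor"),
        junction_frame([("chr1", 100, 200, "+", a),
                        ("chr1", 118, 200, "+", b + c)]),
        ann,
    )
    assert (rec_don.A, rec_don.C) == (a, b + c)
    assert rec_don.usage == pytest.approx(expected)


def test_usage_undefined_without_evidence():
    ann = _toy_annotation()
    rec = compute_usage(_site(100, "donor"), junction_frame([]), ann)
    assert rec.usage is None and not rec.defined


def test_usage_scale_invariance():
    ann = _toy_annotation()
    site = _site(200, "acceptor")
    base = [("chr1", 100, 200, "+", 3), ("chr1", 100, 400, "+", 2)]
    scaled = [(c, s, e, st, n * 10) for c, s, e, st, n in base]
    u1 = compute_usage(site, junction_frame(base), ann).usage
    u2 = compute_usage(site, junction_frame(scaled), ann).usage
    assert u1 == pytest.approx(u2)


def test_usage_table_order_invariant(annotation, junction_samples):
    table = junction_samples["cell1"][1]
    shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
    a = usage_table(annotation, table)
    b = usage_table(annotation, shuffled)
    pd.testing.assert_frame_equal(a, b)


def test_usage_strand_mirror_invariance():
    """Mirroring the toy gene to the - strand leaves every usage value
    unchanged at the corresponding site."""
    counts = {(100, 200): 30, (100, 400): 10, (118, 200): 5, (300, 400): 25}
    for pos, side in [(100, "donor"), (200, "acceptor"), (300, "donor"),
                      (400, "acceptor")]:
        recs = {}
        for strand in "+-":
            ann = _toy_annotation(strand)
            rows = [
                (j.chrom, j.start, j.end, j.strand, n)
                for (s, e), n in counts.items()
                for j in [_jx(s, e, strand)]
            ]
            rec = compute_usage(_site(pos, side, strand),
                                junction_frame(rows), ann)
            recs[strand] = (rec.A, rec.B, rec.C, rec.usage)
        assert recs["+"] == recs["-"]


def test_usage_error_shrinks_with_depth():
    from splicehotspot.synthetic import (
        SimulationConfig,
        simulate_annotation,
        simulate_junction_reads,
    )

    maes = {}
    for depth in (200, 5000):
        cfg = SimulationConfig(seed=9, n_genes=10, read_depth=depth)
        ann, _, truth = simulate_annotation(cfg)
        ut = usage_table(ann, simulate_junction_reads(ann, truth, cfg))
        errs = [
            abs(r.usage - truth.site_usage[(r.chrom, r.pos, r.side, r.strand)])
            for r in ut.itertuples()
            if not np.isnan(r.usage)
            and 0 < truth.site_usage[(r.chrom, r.pos, r.side, r.strand)] < 1
        ]
        maes[depth] = np.mean(errs)
    assert maes[5000] < 0.5 * maes[200]


def _usage_frame(values: dict[tuple, float], sample: str) -> pd.DataFrame:
    rows = [
        (chrom, pos, side, strand, sample, 1, 0, 0, u)
        for (chrom, pos, side, strand), u in values.items()
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "side", "strand", "sample_id",
                 "A", "B", "C", "usage"],
    )


def test_averaged_track_variance_filter():
    site = ("chr1", 100, "donor", "+")
    same = {
        f"line{i}": _usage_frame({site: 0.8}, f"line{i}") for i in range(3)
    }
    track = averaged_track(same)
    assert len(track) == 1
    assert track.loc[0, "variance"] == pytest.approx(0.0, abs=1e-12)
    assert track.loc[0, "mean_usage"] == pytest.approx(0.8)

    split = {
        "a": _usage_frame({site: 0.0}, "a"),
        "b": _usage_frame({site: 1.0}, "b"),
    }
    assert len(averaged_track(split)) == 0  # variance 0.25 >= threshold


def test_averaged_track_matches_bruteforce():
    rng = np.random.default_rng(5)
    sites = [("chr1", int(p), "donor", "+") for p in range(0, 400, 40)]
    lines = {}
    values = {}
    for line in ("l1", "l2", "l3", "l4"):
        vals = {
            s: float(np.round(rng.choice([0.9, 0.9001, rng.uniform()]), 4))
            for s in sites
        }
        values[line] = vals
        lines[line] = _usage_frame(vals, line)
    track = averaged_track(lines, variance_threshold=0.001)
    kept = set()
    for s in sites:
        vv = [values[l][s] for l in lines]
        if np.var(vv) < 0.001:
            kept.add(s[1])
            row = track[track["pos"] == s[1]]
            assert row["mean_usage"].iloc[0] == pytest.approx(np.mean(vv))
    assert set(track["pos"]) == kept


def test_averaged_track_needs_two_lines():
    one = {"only": _usage_frame({("chr1", 1, "donor", "+"): 0.5}, "only")}
    with pytest.raises(ValueError):
        averaged_track(one)


def test_switch_score():
    assert switch_score("e", {"a": 0.4, "b": 0.4, "c": 0.4}).switch_score == 0.0
    rec = switch_score("e", {"a": 0.2, "b": 0.9, "c": 0.5})
    assert rec.switch_score == pytest.approx(0.7)
    single = switch_score("e", {"a": 0.3})
    assert single.switch_score == 0.0 and single.insufficient_conditions


def test_switch_score_matches_pairwise_oracle():
    rng = np.random.default_rng(8)
    psi = {f"c{i}": float(rng.uniform()) for i in range(19)}
    rec = switch_score("e", psi)
    vals = list(psi.values())
    oracle = max(
        abs(vals[i] - vals[j])
        for i in range(len(vals)) for j in range(i + 1, len(vals))
    )
    assert rec.switch_score == pytest.approx(oracle)
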