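"""Feature extraction oracles and the classifier/ablation protocol."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from splicehotspot.classifier import ClassifierConfig, ablation, predict, train
from splicehotspot.features import (
    FeatureTable,
    PwmSpliceScorer,
    apply_variant,
    build_feature_table,
    enumerate_exonic_snvs,
    extract_site_window,
    mean_exon_hexamer_score,
    motif_delta_features,
    mutation_features,
    splice_site_delta_features,
)
from splicehotspot.synthetic import BASES, revcomp

TEST_TREES = 300  # matches the session fixtures in conftest.py


def _exon_row(chrom="chr1", start=30, end=60, strand="+", exon_id="e1",
              transcript_id="t1", gene_id="g1"):
    return pd.Series({
        "exon_id": exon_id, "chrom": chrom, "start": start, "end": end,
        "strand": strand, "transcript_id": transcript_id, "gene_id": gene_id,
    })


def _rand_genome(length=200, seed=0):
    rng = np.random.default_rng(seed)
    return {"chr1": "".join(rng.choice(list(BASES), size=length))}


class _Variant:
    def __init__(self, chrom, pos, ref, alt, strand="+"):
        self.chrom, self.pos, self.ref, self.alt = chrom, pos, ref, alt
        self.strand = strand


def test_enumerate_snvs_three_per_base():
    genome = _rand_genome()
    exon = _exon_row(start=30, end=40)
    variants = enumerate_exonic_snvs(exon, genome)
    assert len(variants) == 30
    for r in variants.itertuples():
        assert r.ref == genome["chr1"][r.pos]
        assert r.alt != r.ref


def test_enumerate_snvs_roundtrip_restores_reference():
    genome = _rand_genome()
    exon = _exon_row(start=30, end=40)
    for r in enumerate_exonic_snvs(exon, genome).itertuples():
        mutated = apply_variant(genome["chr1"], r.pos, r.alt)
        assert mutated != genome["chr1"]
        assert apply_variant(mutated, r.pos, r.ref) == genome["chr1"]


def test_enumerate_snvs_out_of_bounds():
    with pytest.raises(ValueError):
        enumerate_exonic_snvs(_exon_row(start=150, end=260), _rand_genome())


def test_motif_deltas_match_bruteforce():
    genome = _rand_genome(seed=3)
    rng = np.random.default_rng(4)
    hexamers = {}
    v = _Variant("chr1", 50, genome["chr1"][50], "T")
    if v.ref == "T":
        v.alt = "G"
    # random scores for every window that can appear
    for lo in range(40, 60):
        for seq in (genome["chr1"][lo:lo + 6],
                    apply_variant(genome["chr1"], v.pos, v.alt)[lo:lo + 6]):
            hexamers.setdefault(seq, float(rng.normal()))
    feats = motif_delta_features(v, genome, hexamers)
    deltas = []
    mut_chrom = apply_variant(genome["chr1"], v.pos, v.alt)
    for i in range(6):
        lo = v.pos - 5 + i
        wt = genome["chr1"][lo:lo + 6]
        mut = mut_chrom[lo:lo + 6]
        deltas.append(hexamers.get(mut, 0.0) - hexamers.get(wt, 0.0))
    assert feats["hex_delta_sum"] == pytest.approx(sum(deltas))
    assert feats["hex_delta_mean"] == pytest.approx(np.mean(deltas))


def test_motif_deltas_zero_scoring_table():
    genome = _rand_genome()
    v = _Variant("chr1", 50, genome["chr1"][50], "A" if genome["chr1"][50] != "A" else "C")
    feats = motif_delta_features(v, genome, {})
    assert feats["hex_delta_sum"] == 0.0
    assert feats["hex_delta_mean"] == 0.0


class _ConstantScorer:
    name = "constant"

    def donor_score(self, window):
        return 1.0

    def acceptor_score(self, window):
        return 1.0


def test_splice_site_deltas_outside_windows_zero():
    genome = _rand_genome()
    exon = _exon_row(start=30, end=60)
    v = _Variant("chr1", 45, genome["chr1"][45], "A")
    feats = splice_site_delta_features(v, exon, genome, _ConstantScorer())
    assert feats == {"donor_delta": 0.0, "acceptor_delta": 0.0}


def test_splice_site_deltas_constant_scorer_zero_in_window():
    genome = _rand_genome()
    exon = _exon_row(start=30, end=60)
    v = _Variant("chr1", 58, genome["chr1"][58], "A")  # inside donor window
    feats = splice_site_delta_features(v, exon, genome, _ConstantScorer())
    assert feats["donor_delta"] == 0.0


def test_splice_site_delta_matches_pwm_arithmetic():
    """Delta equals the hand-computed log-odds difference at the mutated
    window position."""
    genome = _rand_genome(seed=9)
    exon = _exon_row(start=30, end=60)
    donor = np.zeros((9, 4))
    donor[:, BASES.index("G")] = 1.5   # G scores 1.5 at every position
    scorer = PwmSpliceScorer(donor, np.zeros((23, 4)))
    pos = 58  # exonic donor-window position (window is [57, 66))
    ref = genome["chr1"][pos]
    alt = "G" if ref != "G" else "A"
    v = _Variant("chr1", pos, ref, alt)
    feats = splice_site_delta_features(v, exon, genome, scorer)
    expected = (1.5 if alt == "G" else 0.0) - (1.5 if ref == "G" else 0.0)
    assert feats["donor_delta"] == pytest.approx(expected)


def test_site_window_extraction_strandedness():
    genome = {"chr1": "".join("ACGT"[i % 4] for i in range(100))}
    w_plus = extract_site_window("chr1", 50, "donor", "+", genome)
    assert w_plus == genome["chr1"][47:56]
    w_minus = extract_site_window("chr1", 50, "donor", "-", genome)
    assert w_minus == revcomp(genome["chr1"][44:53])
    assert extract_site_window("chr1", 1, "acceptor", "+", genome) is None


def test_mean_exon_hexamer_window_count():
    genome = _rand_genome(seed=5)
    exon = _exon_row(start=30, end=60)  # L = 30 -> 25 hexamers
    seq = genome["chr1"][30:60]
    hexamers = {seq[i:i + 6]: float(i) for i in range(25)}
    got = mean_exon_hexamer_score(exon, genome, hexamers)
    assert got == pytest.approx(
        np.mean([hexamers[seq[i:i + 6]] for i in range(25)])
    )


def test_mutation_features_one_hot():
    v = _Variant("chr1", 10, "G", "T")
    feats = mutation_features(v)
    assert feats["sub_GtoT"] == 1.0
    assert sum(feats.values()) == 1.0
    # transcript orientation: on the minus strand G>T reads as C>A
    v_minus = _Variant("chr1", 10, "G", "T", strand="-")
    assert mutation_features(v_minus)["sub_CtoA"] == 1.0


def test_mutation_one_hot_sums_to_one(feature_table):
    sub_cols = [c for c in feature_table.frame.columns if c.startswith("sub_")]
    assert len(sub_cols) == 12
    assert (feature_table.frame[sub_cols].sum(axis=1) == 1.0).all()


def test_structure_plugin_changes_feature_count():
    genome = _rand_genome()
    v = _Variant("chr1", 50, genome["chr1"][50], "A")
    base = mutation_features(v)
    with_plugin = mutation_features(
        v, structure_scorer=lambda _v: {"hyb_wt": 1.0, "hyb_mut": 0.0}
    )
    assert len(with_plugin) == len(base) + 2


def test_feature_groups_partition(feature_table):
    assert set(feature_table.groups.values()) == {
        "mutation", "motif", "exon", "transcript",
    }
    assert set(feature_table.groups) == set(feature_table.frame.columns)


def test_feature_extraction_strand_consistent(annotation, genome, exons,
                                              hexamers, truth):
    """Features of a minus-strand gene's variants are computed in
    transcript orientation: mirroring the genome and annotation to the
    plus strand yields identical values."""
    minus = exons[(exons["strand"] == "-") & exons["internal"]].iloc[0]
    chrom_len = len(genome[minus["chrom"]])
    variants = enumerate_exonic_snvs(minus, genome).head(12)

    # mirrored world: reverse-complement the chromosome, flip coordinates
    from splicehotspot.annotation import Annotation, Exon, Gene, Transcript

    m_genome = {minus["chrom"]: revcomp(genome[minus["chrom"]])}
    gene = annotation.genes[minus["gene_id"]]
    m_gene = Gene(gene.gene_id, gene.chrom, "+")
    for tid, t in gene.transcripts.items():
        mt = Transcript(tid, t.gene_id, t.chrom, "+")
        for e in t.exons:
            mt.exons.append(
                Exon(e.chrom, chrom_len - e.end, chrom_len - e.start, "+")
            )
        m_gene.transcripts[tid] = mt
    m_ann = Annotation({m_gene.gene_id: m_gene})
    m_exon_row = pd.DataFrame([{
        "exon_id": minus["exon_id"], "chrom": minus["chrom"],
        "start": chrom_len - minus["end"], "end": chrom_len - minus["start"],
        "strand": "+", "transcript_id": minus["transcript_id"],
        "gene_id": minus["gene_id"],
    }])
    m_variants = variants.copy()
    m_variants["pos"] = chrom_len - 1 - variants["pos"]
    m_variants["ref"] = [revcomp(b) for b in variants["ref"]]
    m_variants["alt"] = [revcomp(b) for b in variants["alt"]]
    m_variants["strand"] = "+"

    exon_row = exons[exons["exon_id"] == minus["exon_id"]]
    ft = build_feature_table(variants, exon_row, annotation, genome, hexamers)
    m_ft = build_feature_table(m_variants, m_exon_row, m_ann, m_genome,
                               hexamers)
    for col in ("hex_delta_sum", "hex_delta_mean", "exon_length",
                "exon_mean_hexamer", "n_exons"):
        np.testing.assert_allclose(
            ft.frame[col].to_numpy(), m_ft.frame[col].to_numpy(),
            atol=1e-9, err_msg=col,
        )
    sub_cols = [c for c in ft.frame.columns if c.startswith("sub_")]
    pd.testing.assert_frame_equal(
        ft.frame[sub_cols].reset_index(drop=True),
        m_ft.frame[sub_cols].reset_index(drop=True),
    )


def _noise_table(n=200, n_features=5, seed=0):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        rng.normal(size=(n, n_features)),
        columns=[f"f{i}" for i in range(n_features)],
        index=[f"v{i}" for i in range(n)],
    )
    groups = {f"f{i}": "exon" for i in range(n_features)}
    return FeatureTable(frame, groups, frame.index.to_frame(name="variant_id"))


def test_train_rejects_single_class():
    table = _noise_table()
    with pytest.raises(ValueError):
        train(table, np.ones(len(table.frame)), ClassifierConfig(n_trees=10))


def test_perfect_feature_reaches_auc_one():
    table = _noise_table(n=200)
    y = (table.frame["f0"] > 0).to_numpy().astype(int)
    tm = train(table, y, ClassifierConfig(n_trees=50, seed=1))
    assert tm.heldout_auc == 1.0


def test_null_auc_centered_at_half():
    """Labels shuffled against features: mean held-out AUC over 20 seeds
    sits at chance level."""
    rng = np.random.default_rng(42)
    table = _noise_table(n=300, seed=2)
    aucs = []
    for seed in range(20):
        y = rng.permutation([0, 1] * 150)
        tm = train(table, y, ClassifierConfig(n_trees=50, seed=seed,
                                              cv_folds=2))
        aucs.append(tm.heldout_auc)
    assert 0.45 <= float(np.mean(aucs)) <= 0.55


def test_synthetic_signal_auc(trained_model):
    assert trained_model.heldout_auc > 0.85
    assert trained_model.cv_auc > 0.75


def test_manifest_records_protocol(trained_model):
    m = trained_model.manifest
    assert m["config"]["train_fraction"] == pytest.approx(0.70)
    assert set(m["feature_groups"].values()) <= {
        "mutation", "motif", "exon", "transcript", "derived",
    }
    assert set(m["imputation_medians"]) == set(m["feature_names"])


def test_ablation_planted_exon_signal(feature_table, labels):
    res = ablation(feature_table, labels,
                   ClassifierConfig(n_trees=TEST_TREES, seed=0))
    auc = res.set_index("variant_set")["heldout_auc"]
    full = auc["full"]
    assert full - auc["without_exon"] > 0.1
    for g in ("motif", "mutation", "transcript"):
        assert abs(full - auc[f"without_{g}"]) < 0.03
    only = {g: auc[f"only_{g}"] for g in ("exon", "motif", "mutation",
                                          "transcript")}
    assert only["exon"] == max(only.values())


def test_ablation_constant_group_leave_out_is_noop():
    table = _noise_table(n=200, n_features=4, seed=3)
    y = (table.frame["f0"] + 0.5 * np.random.default_rng(0).normal(size=200)
         > 0).astype(int)
    table.frame["const1"] = 1.0
    table.frame["const2"] = 0.0
    table.groups.update({"const1": "motif", "const2": "motif"})
    res = ablation(table, y, ClassifierConfig(n_trees=50, seed=2))
    auc = res.set_index("variant_set")["heldout_auc"]
    assert round(auc["full"], 3) == round(auc["without_motif"], 3)


def test_predict_cutoff_strict(trained_model, feature_table):
    out = predict(trained_model, feature_table)
    # the decision rule itself: strictly above 0.5
    assert (out["call"] == (out["score"] > 0.5)).all()
    # row-order invariance
    reordered = FeatureTable(
        feature_table.frame.iloc[::-1], feature_table.groups,
        feature_table.meta.iloc[::-1],
    )
    out_rev = predict(trained_model, reordered)
    merged = out.set_index("variant_id")["score"]
    for r in out_rev.itertuples():
        assert merged[r.variant_id] == pytest.approx(r.score)


def test_imputation_with_missing_features(feature_table, labels):
    frame = feature_table.frame.copy()
    frame.loc[frame.index[:40], "donor_usage"] = np.nan
    table = FeatureTable(frame, dict(feature_table.groups),
                         feature_table.meta)
    tm = train(table, labels, ClassifierConfig(n_trees=50, seed=0))
    assert "donor_usage_missing" in tm.feature_names
    assert tm.manifest["imputation_medians"]["donor_usage"] is not None
    assert tm.heldout_auc > 0.7
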