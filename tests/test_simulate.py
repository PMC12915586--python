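"""The synthetic-study generator: determinism, anchor traits, controlled
divergence, and the planted compositional structure."""
import numpy as np
import pandas as pd
import pytest

import amplitrait as at
from amplitrait.simulate import otu_id_for
from amplitrait.stats import spearman_trend


def test_same_seed_reproduces_reference_and_counts():
    a = at.simulate_study(seed=11)
    b = at.simulate_study(seed=11)
    assert [(r.accession, r.sequence, r.genome_size_mb, r.rrn) for r in a.reference] == [
        (r.accession, r.sequence, r.genome_size_mb, r.rrn) for r in b.reference
    ]
    pd.testing.assert_frame_equal(a.counts, b.counts)
    assert a.otus == b.otus


def test_anchor_taxa_carry_exemplar_traits(bundle):
    truth = bundle.truth.set_index("otu_id")
    late = truth[truth["guild"] == "late_slow"].iloc[0]
    early = truth[truth["guild"] == "early_fast"].iloc[0]
    assert (late["genome_size_mb"], late["rrn"]) == (8.817, 2)
    assert (early["genome_size_mb"], early["rrn"]) == (5.778, 3)


def test_guild_trait_ordering_enforced():
    turnover = at.default_turnover()
    guilds = {g.name: g for g in turnover.guilds}
    assert guilds["late_slow"].genome_size_mean_mb > guilds["early_fast"].genome_size_mean_mb
    with pytest.raises(ValueError, match="late_slow"):
        at.TurnoverSpec(
            guilds=(
                at.GuildSpec("late_slow", 0.5, 4.0, 0.5, (5,)),
                at.GuildSpec("early_fast", 0.5, 8.0, 0.5, (2,)),
            )
        )


def test_amplicon_identity_targets():
    reference, guild_map = at.simulate_reference(4, at.default_turnover(), seed=3)
    accs = reference.accessions
    # exact copy at target 1.0
    otus, _ = at.simulate_amplicons(reference, {a: 1.0 for a in accs}, seed=3)
    for (otu, seq), acc in zip(otus, accs):
        assert seq == reference[acc].sequence
    # target 0.94 places round(0.06 * L) substitutions
    otus, _ = at.simulate_amplicons(reference, {a: 0.94 for a in accs}, seed=3)
    for (otu, seq), acc in zip(otus, accs):
        ref = reference[acc].sequence
        n_sub = sum(a != b for a, b in zip(seq, ref))
        assert n_sub == round(0.06 * len(ref))
    with pytest.raises(ValueError, match="outside"):
        at.simulate_amplicons(reference, {accs[0]: 0.3}, seed=3)


def test_unrelated_otus_exact_count():
    reference, guild_map = at.simulate_reference(50, at.default_turnover(), seed=5)
    unrelated = reference.accessions[:10]
    otus, otu_map = at.simulate_amplicons(reference, 1.0, unrelated, seed=5)
    assert sum(v is None for v in otu_map.values()) == 10
    for acc in unrelated:
        assert otu_map[otu_id_for(acc)] is None


def test_counts_are_integers_within_depth_range(bundle):
    design = at.StudyDesign()
    totals = bundle.counts.sum(axis=1)
    assert (bundle.counts.to_numpy() >= 0).all()
    assert totals.between(*design.depth_range).all()


def test_flat_turnover_gives_time_constant_composition():
    flat = at.TurnoverSpec(
        guilds=(at.GuildSpec("background", 1.0, 5.5, 0.8, (3,)),),
        dirichlet_concentration=None,
    )
    design = at.StudyDesign(n_time_points=3, n_sites=1, replicates=1)
    _, guild_map = at.simulate_reference(5, flat, seed=1)
    _, meta, expected = at.simulate_counts(
        design, flat, guild_map, seed=1, return_expected=True
    )
    for comp in design.compartments:
        sub = expected.loc[meta[meta["compartment"] == comp].index]
        assert np.allclose(sub.to_numpy(), sub.to_numpy()[0], atol=1e-12)


def test_planted_root_turnover_detected_in_generated_table(bundle):
    """Summed late_slow relative abundance rises with time in roots."""
    truth = bundle.truth
    late = truth[truth["guild"] == "late_slow"]["otu_id"]
    rel = bundle.counts.div(bundle.counts.sum(axis=1), axis=0)
    meta = bundle.metadata
    root = meta[meta["compartment"] == "root"].index
    res = spearman_trend(
        meta.loc[root, "time_point"].to_numpy(float),
        rel.loc[root, late].sum(axis=1).to_numpy(),
    )
    assert res.rho > 0.5 and res.p_value < 1e-6


def test_treatment_factor_suppresses_fast_guild():
    """A treatment factor below one lowers the early_fast guild's expected
    relative abundance under N addition at every time point and site."""
    turnover = at.default_turnover()
    design = at.StudyDesign(replicates=1)
    _, guild_map = at.simulate_reference(12, turnover, seed=6)
    _, meta, expected = at.simulate_counts(
        design, turnover, guild_map, seed=6, return_expected=True
    )
    fast = [acc for acc, g in guild_map.items() if g == "early_fast"]
    share = expected[fast].sum(axis=1)
    root = meta[meta["compartment"] == "root"]
    for (tp, site), sub in root.groupby(["time_point", "site"]):
        ctrl = share.loc[sub[sub["treatment"] == "control"].index].iloc[0]
        nadd = share.loc[sub[sub["treatment"] == "N_addition"].index].iloc[0]
        assert nadd < ctrl


def test_noise_free_composition_converges_with_depth():
    turnover = at.TurnoverSpec(guilds=at.default_turnover().guilds, dirichlet_concentration=None)
    design = at.StudyDesign(
        n_time_points=2, n_sites=1, replicates=1, depth_range=(200_000, 200_000)
    )
    _, guild_map = at.simulate_reference(10, turnover, seed=2)
    counts, meta, expected = at.simulate_counts(
        design, turnover, guild_map, seed=2, return_expected=True
    )
    rel = counts.div(counts.sum(axis=1), axis=0)
    # multinomial sd per taxon is ~sqrt(p/depth) < 1/sqrt(depth); allow 6 sigma
    assert np.abs(rel.to_numpy() - expected.to_numpy()).max() < 6 / np.sqrt(200_000)


def test_perfect_assignment_trait_trend_sign(bundle):
    """With ground-truth traits, the community-weighted genome size rises in
    roots and stays flat in air."""
    truth = bundle.truth.set_index("otu_id")
    gs = truth["genome_size_mb"]
    rel = bundle.counts.div(bundle.counts.sum(axis=1), axis=0)
    cwm = rel @ gs.loc[rel.columns]
    meta = bundle.metadata
    trends = {}
    for comp in ("root", "air"):
        idx = meta[meta["compartment"] == comp].index
        trends[comp] = spearman_trend(
            meta.loc[idx, "time_point"].to_numpy(float), cwm.loc[idx].to_numpy()
        ).rho
    assert trends["root"] > 0.5
    assert abs(trends["air"]) < 0.25


def test_design_validation_errors():
    with pytest.raises(ValueError, match="time points"):
        at.StudyDesign(n_time_points=1)
    with pytest.raises(ValueError, match="depth"):
        at.StudyDesign(depth_range=(0, 100))
    with pytest.raises(ValueError, match="n_taxa"):
        at.simulate_reference(2, at.default_turnover(), seed=0)


def test_missing_cells_emulate_unbalanced_design():
    design = at.StudyDesign(missing_cells=(("root", 1, "control", 1),))
    turnover = at.default_turnover()
    _, guild_map = at.simulate_reference(6, turnover, seed=4)
    _, meta = at.simulate_counts(design, turnover, guild_map, seed=4)
    cell = meta[
        (meta["compartment"] == "root")
        & (meta["time_point"] == 1)
        & (meta["treatment"] == "control")
        & (meta["site"] == 1)
    ]
    assert cell.empty
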