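import numpy as np
import pytest

import subdrift as sd
from subdrift.simulate import DEFAULT_POOLS


# ----------------------------------------------------------------------
# drift
# ----------------------------------------------------------------------

def test_zero_rate_gives_empty_table(schedule):
    table, truth = sd.simulate_drift(schedule, sd.DriftParams(lambda_fix=0.0, seed=1))
    assert len(table) == 0
    m = sd.pairwise_distance(table, "all")
    assert np.all(m.values == 0)
    assert all(n == 0 for _, n in truth.values())


def test_negative_rate_rejected(schedule):
    with pytest.raises(ValueError, match="lambda_fix"):
        sd.simulate_drift(schedule, sd.DriftParams(lambda_fix=-0.1))


def test_single_tip_schedule_rejected():
    root = sd.ScheduleNode(
        date=2000, children=[sd.ScheduleNode(name="A"), sd.ScheduleNode(name="B")]
    )
    sch = sd.SeparationSchedule(root, 2014)
    sch.root.children = sch.root.children[:1]  # degrade to 1 tip
    with pytest.raises(ValueError):
        sd.simulate_drift(sch, sd.DriftParams())


def test_no_heterozygous_and_carriers_match_truth(drift_table):
    table, truth = drift_table
    # calls are strictly boolean (ref/alt homozygous): carriers of every
    # variant are exactly the tips below its originating branch
    observed_sdps = {}
    names = np.array(table.substrains)
    for i in range(len(table)):
        key = frozenset(names[table.calls[i]])
        observed_sdps[key] = observed_sdps.get(key, 0) + 1
    for tipset, (_, n) in truth.items():
        assert observed_sdps.get(tipset, 0) == n


def test_two_tip_mean_distance_matches_poisson_theory(two_tip_schedule):
    # each lineage: 100 generations; lambda 0.25 -> E[pairwise distance] = 50
    lam, g, reps = 0.25, 100, 1000
    dists = np.empty(reps)
    for s in range(reps):
        table, _ = sd.simulate_drift(
            two_tip_schedule, sd.DriftParams(lambda_fix=lam, seed=s)
        )
        dists[s] = sd.pairwise_distance(table, "all").values[0, 1]
    expected = 2 * g * lam
    se = np.sqrt(expected / reps)  # Poisson variance = mean
    assert abs(dists.mean() - expected) < 3 * se


def test_cherry_pair_has_smallest_expected_distance(schedule):
    # ShiLt/ShiLtDvs split last: smallest path length, hence smallest
    # expected distance; check the Monte-Carlo mean ordering
    reps = 200
    tot = np.zeros((5, 5))
    for s in range(reps):
        table, _ = sd.simulate_drift(schedule, sd.DriftParams(seed=s))
        tot += sd.pairwise_distance(table, "all").values
    labels = schedule.substrain_names
    i, j = labels.index("ShiLt"), labels.index("ShiLtDvs")
    cherry = tot[i, j]
    off = [
        tot[a, b]
        for a in range(5)
        for b in range(a + 1, 5)
        if {a, b} != {i, j}
    ]
    assert cherry < min(off)


def test_drift_bit_reproducible(schedule):
    t1, _ = sd.simulate_drift(schedule, sd.DriftParams(seed=7))
    t2, _ = sd.simulate_drift(schedule, sd.DriftParams(seed=7))
    assert t1 == t2
    t3, _ = sd.simulate_drift(schedule, sd.DriftParams(seed=8))
    assert not (t1 == t3)


def test_positions_unique(drift_table):
    table, _ = drift_table
    keys = list(zip(table.variants["chrom"], table.variants["pos"]))
    assert len(keys) == len(set(keys))


# ----------------------------------------------------------------------
# pooled reads
# ----------------------------------------------------------------------

def _informative_snp_loci(table, n=None):
    snp = np.flatnonzero(table.class_mask("SNP"))
    loci = [int(i) for i in snp if 0 < table.calls[i].sum() < table.n_substrains]
    return loci if n is None else loci[:n]


def test_noiseless_reads_carry_focal_allele(drift_table):
    table, _ = drift_table
    loci = _informative_snp_loci(table, 5)
    design = sd.PoolDesign(depth_per_strain=100, error_rate=0.0, jump_rate=0.0, seed=1)
    pileup = sd.simulate_pooled_reads(table, loci, design)
    rates = sd.estimate_artifact_rates(pileup, pileup.loci(), table)
    assert np.all(rates.cells["focal_freq"] == 1.0)
    assert np.all(rates.cells["jump_freq"] == 0.0)
    assert np.all(rates.cells["error_freq"] == 0.0)


def test_counts_sum_to_depth(drift_table):
    table, _ = drift_table
    loci = _informative_snp_loci(table, 10)
    design = sd.PoolDesign(depth_per_strain=333, error_rate=0.01, jump_rate=0.05, seed=3)
    pileup = sd.simulate_pooled_reads(table, loci, design)
    totals = pileup.records[["count_A", "count_C", "count_G", "count_T"]].sum(axis=1)
    assert np.all(totals == 333)


def _two_strain_panel(n_loci=30):
    """Two substrains in one pool, differing at every locus."""
    import pandas as pd

    variants = pd.DataFrame(
        {
            "chrom": ["1"] * n_loci,
            "pos": np.arange(1, n_loci + 1) * 10,
            "ref": ["A"] * n_loci,
            "alt": ["G"] * n_loci,
            "vclass": ["SNP"] * n_loci,
        }
    )
    calls = np.zeros((n_loci, 2), dtype=bool)
    calls[:, 1] = True
    return sd.GenotypeTable(variants, calls, ["X", "Y"])


def test_jump_rate_recovered_binomial():
    table = _two_strain_panel()
    j, depth = 0.02, 10_000
    design = sd.PoolDesign(
        pools={"p": ["X", "Y"]}, depth_per_strain=depth, error_rate=0.0,
        jump_rate=j, seed=5,
    )
    pileup = sd.simulate_pooled_reads(table, list(range(len(table))), design)
    rates = sd.estimate_artifact_rates(pileup, pileup.loci(), table)
    n = len(rates.cells) * depth
    se = np.sqrt(j * (1 - j) / n)
    assert abs(rates.cells["jump_freq"].mean() - j) < 3 * se


def test_error_rate_uniform_over_alternatives():
    # no jumping: each of the 3 non-focal bases receives e/3 of the reads
    table = _two_strain_panel()
    e, depth = 0.003, 10_000
    design = sd.PoolDesign(
        pools={"p": ["X", "Y"]}, depth_per_strain=depth, error_rate=e,
        jump_rate=0.0, seed=9,
    )
    pileup = sd.simulate_pooled_reads(table, list(range(len(table))), design)
    # strain X is homozygous A everywhere; C and T are never another
    # strain's allele, so each should appear at frequency e/3
    x = pileup.records[pileup.records["substrain"] == "X"]
    n = len(x) * depth
    for base in ("C", "T"):
        freq = x[f"count_{base}"].sum() / n
        se = np.sqrt((e / 3) * (1 - e / 3) / n)
        assert abs(freq - e / 3) < 3 * se


def test_invalid_pool_design(drift_table):
    table, _ = drift_table
    with pytest.raises(ValueError, match="<= 1"):
        sd.PoolDesign(error_rate=0.6, jump_rate=0.5).validate(table.substrains)
    bad = sd.PoolDesign(pools={"p1": ["ShiLt"], "p2": ["ShiLt", "BomTac"]})
    with pytest.raises(ValueError, match="disjoint"):
        bad.validate()


def test_pooled_reads_reproducible(drift_table):
    table, _ = drift_table
    loci = _informative_snp_loci(table, 5)
    d = sd.PoolDesign(seed=11)
    p1 = sd.simulate_pooled_reads(table, loci, d)
    p2 = sd.simulate_pooled_reads(table, loci, d)
    assert p1.records.equals(p2.records)


# ----------------------------------------------------------------------
# intensities
# ----------------------------------------------------------------------

def test_null_track_centers_near_zero():
    spec = sd.CnvSpec(n_probes=400, noise_sd=0.1, seed=2)
    track = sd.simulate_intensities(spec, list(DEFAULT_POOLS["poolA"]))
    for s in track.substrains:
        assert abs(track.data[s].mean()) < 3 * 0.1 / np.sqrt(400)


def test_planted_deletion_mean_shift():
    delta, n_del = -2.0, 13
    spec = sd.CnvSpec(
        n_probes=100, deletions=[({"ShiLtDvs"}, (40, 53), delta)],
        noise_sd=0.1, seed=4,
    )
    track = sd.simulate_intensities(spec, ["ShiLt", "ShiLtDvs", "BomTac"])
    affected = track.data["ShiLtDvs"].to_numpy()[40:53]
    se = 0.1 / np.sqrt(n_del)
    assert abs(affected.mean() - delta) < 3 * se


def test_unaffected_substrains_stay_null():
    # deletion planted in 2 of 5 substrains; the other 3 should be
    # indistinguishable from pure noise (two-sample t-test at alpha=0.01
    # passes in >=95% of seeds)
    from scipy.stats import ttest_ind

    strains = ["A", "B", "C", "D", "E"]
    n_pass = 0
    seeds = 200
    for s in range(seeds):
        spec = sd.CnvSpec(
            n_probes=60, deletions=[({"A", "B"}, (20, 33), -2.0)],
            noise_sd=0.1, seed=s,
        )
        track = sd.simulate_intensities(spec, strains)
        null = sd.simulate_intensities(
            sd.CnvSpec(n_probes=60, noise_sd=0.1, seed=10_000 + s), strains
        )
        ok = all(
            ttest_ind(track.data[x], null.data[x]).pvalue > 0.01
            for x in ("C", "D", "E")
        )
        n_pass += ok
    assert n_pass >= 0.95 * seeds


def test_invalid_cnv_specs():
    with pytest.raises(ValueError, match="negative"):
        sd.CnvSpec(deletions=[({"A"}, (0, 5), 1.0)]).validate()
    with pytest.raises(ValueError, match="outside"):
        sd.CnvSpec(n_probes=10, deletions=[({"A"}, (5, 20), -1.0)]).validate()
    with pytest.raises(ValueError, match="increase"):
        sd.CnvSpec(n_probes=3, probe_positions=[10, 5, 20]).validate()
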