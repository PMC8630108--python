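"""Tests of CNA profile inference, subclone calling, and clone dynamics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from mmscope import cna, io_core, synthetic
from mmscope.synthetic import CNAEvent, PatientSim, SimConfig, SubcloneSim
from conftest import make_adata


def _toy_order(n_per_chrom=(6, 6), chroms=("1", "2")):
    rows = []
    for chrom, n in zip(chroms, n_per_chrom):
        for i in range(n):
            arm = f"{chrom}p" if i < n // 2 else f"{chrom}q"
            rows.append((f"g_{chrom}_{i}", chrom, (i + 1) * 100, (i + 1) * 100 + 10, arm))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "arm"])


class TestInferProfiles:
    def test_matches_brute_force_oracle(self):
        """The vectorized pipeline equals a literal step-by-step re-computation
        (cutoff, reference centering, clipping, shrinking-window moving
        average per chromosome, median recentering)."""
        rng = np.random.default_rng(0)
        order = _toy_order((9, 7))
        n_cells, n_genes = 40, len(order)
        x = rng.gamma(2.0, 1.0, size=(n_cells, n_genes))
        adata = make_adata(np.zeros((n_cells, n_genes)), gene_ids=list(order["gene"]))
        adata.X = x  # dense normalized values, used directly
        ref = [f"cell{i}" for i in range(30)]
        window, clip_sd, cutoff = 5, 3.0, 0.1
        prof = cna.infer_cna_profiles(adata, order, ref, mean_cutoff=cutoff,
                                      window=window, clip_sd=clip_sd)

        keep = x.mean(axis=0) >= cutoff
        xs = x[:, keep]
        kept_order = order.loc[keep].reset_index(drop=True)
        mu = xs[:30].mean(axis=0)
        sd = xs[:30].std(axis=0, ddof=1)
        resid = np.clip(xs - mu, -clip_sd * sd, clip_sd * sd)
        expected = np.empty_like(resid)
        for chrom in ["1", "2"]:
            idx = np.flatnonzero((kept_order["chrom"] == chrom).to_numpy())
            n, start = len(idx), idx[0]
            for j in range(n):
                h = min(window // 2, j, n - 1 - j)
                expected[:, start + j] = resid[:, start + j - h : start + j + h + 1].mean(axis=1)
        expected -= np.median(expected, axis=1, keepdims=True)
        np.testing.assert_allclose(prof.signal.to_numpy(), expected, atol=1e-12)

    def test_too_few_reference_cells_raises(self):
        order = _toy_order()
        adata = make_adata(np.ones((40, len(order))), gene_ids=list(order["gene"]))
        with pytest.raises(ValueError, match="30 reference cells"):
            cna.infer_cna_profiles(adata, order, ["cell0"], window=3)

    def test_too_few_retained_genes_raises(self):
        order = _toy_order()
        adata = make_adata(np.ones((40, len(order))), gene_ids=list(order["gene"]))
        with pytest.raises(ValueError, match="pass the mean-expression cutoff"):
            cna.infer_cna_profiles(adata, order, [f"cell{i}" for i in range(30)],
                                   window=101)

    def test_reference_cells_center_near_zero(self, three_clone):
        ref_mean = three_clone.profiles.signal.loc[
            three_clone.profiles.reference_ids
        ].mean(axis=0)
        assert ref_mean.abs().max() <= 0.02

    def test_planted_gain_positive_loss_negative(self, three_clone):
        prof, truth = three_clone.profiles, three_clone.truth
        sig = prof.signal.loc[prof.tumor_ids].to_numpy()
        b = (truth == "B").to_numpy()
        gain = sig[:, prof.arm_gene_mask("3q")].mean()  # diluted by neutral clones
        assert sig[b][:, prof.arm_gene_mask("3q")].mean() > sig[~b][:, prof.arm_gene_mask("3q")].mean()
        assert sig[b][:, prof.arm_gene_mask("13q")].mean() < 0


class TestCallSubclones:
    def test_two_planted_clones_recovered_exactly(self):
        cfg = SimConfig(
            seed=7, junk_cell_frac=0.0, doublet_frac=0.0,
            patients=[PatientSim("T", 1000, 0, 60, 0, 0, subclones=[
                SubcloneSim("a", 0.5, 0.5, []),
                # two aberrations give a per-cell margin wide enough for
                # error-free assignment at this depth
                SubcloneSim("b", 0.5, 0.5, [CNAEvent("7q", 3), CNAEvent("4q", 1)]),
            ])],
        )
        ds = synthetic.simulate_cohort(cfg)
        norm = io_core.normalize_log(io_core.qc_filter(ds.adata))
        ref = list(norm.obs_names[norm.obs["cell_type"] == "nPC"])
        prof = cna.infer_cna_profiles(norm, ds.gene_order, ref)
        sub = cna.call_subclones(prof)
        truth = ds.adata.obs.loc[prof.tumor_ids, "subclone"]
        assert len(sub.subclone_ids) == 2
        assert adjusted_rand_score(truth, sub.labels.loc[truth.index]) == 1.0

    def test_no_planted_structure_gives_single_clone(self):
        cfg = SimConfig(
            seed=8, junk_cell_frac=0.0, doublet_frac=0.0,
            patients=[PatientSim("T", 600, 0, 60, 0, 0, subclones=[
                SubcloneSim("only", 1.0, 1.0, []),
            ])],
        )
        ds = synthetic.simulate_cohort(cfg)
        norm = io_core.normalize_log(io_core.qc_filter(ds.adata))
        ref = list(norm.obs_names[norm.obs["cell_type"] == "nPC"])
        sub = cna.call_subclones(cna.infer_cna_profiles(norm, ds.gene_order, ref))
        assert len(sub.subclone_ids) == 1

    def test_minor_clone_below_floor_absorbed(self, minor_clone):
        assert len(minor_clone.subclones.subclone_ids) == 2
        assert (minor_clone.subclones.sizes >= 40).all()
        # the 30 planted 1q cells were merged into a 1q-neutral neighbour
        assert cna.fraction_aberrant_cells(minor_clone.subclones, "1q") == 0.0

    def test_fewer_than_min_cells_returns_flagged_single_clone(self, three_clone):
        keep = three_clone.profiles.reference_ids + list(three_clone.profiles.tumor_ids[:20])
        small = cna.CNAProfileMatrix(
            signal=three_clone.profiles.signal.loc[keep],
            gene_order=three_clone.profiles.gene_order,
            window=three_clone.profiles.window,
            reference_ids=three_clone.profiles.reference_ids,
        )
        with pytest.warns(UserWarning, match="single subclone"):
            sub = cna.call_subclones(small)
        assert sub.single_clone_fallback


class TestRegionStatesAndFractions:
    def test_states_on_planted_fixture(self, three_clone):
        states = three_clone.subclones.arm_states
        by_truth = {}
        for sc in three_clone.subclones.subclone_ids:
            cells = three_clone.subclones.labels[three_clone.subclones.labels == sc].index
            by_truth[three_clone.truth.loc[cells].mode()[0]] = sc
        assert states.loc[by_truth["A"]].eq("neutral").all()
        assert states.loc[by_truth["B"], "3q"] == "gain"
        assert states.loc[by_truth["B"], "13q"] == "loss"
        assert states.loc[by_truth["C"], "11q"] == "gain"

    def test_absent_arm_raises(self, three_clone):
        with pytest.raises(KeyError, match="no retained genes"):
            cna.call_region_state(three_clone.subclones, "Zq")

    def test_fraction_trivial_cases(self, three_clone):
        every_gained = _fake_subclone_set(
            {"A": [1] * 5 + [0] * 5, "B": [1] * 5 + [0] * 5},
            {"A": "gain", "B": "gain"},
        )
        assert cna.fraction_aberrant_cells(every_gained, "1q") == 1.0
        # nothing planted on 1q in the three-clone fixture
        assert cna.fraction_aberrant_cells(three_clone.subclones, "1q") == 0.0

    def test_fraction_invariant_to_relabeling(self, minor_clone):
        sub = minor_clone.subclones
        f1 = cna.fraction_aberrant_cells(sub, "5q")
        relabel = {"SC1": "X2", "SC2": "X1"}
        sub2 = cna.SubcloneSet(
            labels=sub.labels.map(relabel),
            profiles=sub.profiles.rename(index=relabel),
            sizes=sub.sizes.rename(index=relabel),
            arm_states=sub.arm_states.rename(index=relabel),
            cna=sub.cna,
        )
        assert cna.fraction_aberrant_cells(sub2, "5q") == f1


class TestClassify1q:
    @pytest.mark.parametrize(
        "fraction,expected",
        [
            (0.0, "ND_rare"), (0.05, "ND_rare"), (0.0999, "ND_rare"),
            (0.10, "subclonal"), (0.50, "subclonal"), (0.80, "subclonal"),
            (0.8001, "dominant"), (0.90, "dominant"), (1.0, "dominant"),
        ],
    )
    def test_band_convention(self, fraction, expected):
        assert cna.classify_1q_group(fraction) == expected

    @pytest.mark.parametrize("bad", [-0.01, 1.01])
    def test_out_of_range_raises(self, bad):
        with pytest.raises(ValueError):
            cna.classify_1q_group(bad)


def _fake_subclone_set(profiles: dict, states_1q: dict, arm_genes=5, other_genes=5):
    genes = [f"q{i}" for i in range(arm_genes)] + [f"o{i}" for i in range(other_genes)]
    order = pd.DataFrame({
        "gene": genes,
        "chrom": ["1"] * arm_genes + ["2"] * other_genes,
        "start": range(len(genes)),
        "arm": ["1q"] * arm_genes + ["2q"] * other_genes,
    })
    prof_df = pd.DataFrame(profiles, index=genes).T
    ref_ids = [f"r{i}" for i in range(30)]
    rng = np.random.default_rng(0)
    sig = pd.DataFrame(
        rng.normal(0, 0.01, size=(30, len(genes))), index=ref_ids, columns=genes
    )
    cpm = cna.CNAProfileMatrix(signal=sig, gene_order=order, window=1, reference_ids=ref_ids)
    labels = pd.Series({f"c_{k}": k for k in profiles})
    return cna.SubcloneSet(
        labels=labels,
        profiles=prof_df,
        sizes=labels.value_counts(),
        arm_states=pd.DataFrame({"1q": pd.Series(states_1q)}),
        cna=cpm,
    )


class TestMatchClosestClone:
    def test_single_neutral_candidate(self):
        sub = _fake_subclone_set(
            {"T": [1] * 5 + [0.5] * 5, "N": [0] * 10},
            {"T": "gain", "N": "neutral"},
        )
        assert cna.match_closest_clone(sub, "T") == "N"

    def test_brute_force_minimum_distance(self):
        rng = np.random.default_rng(3)
        profiles = {"T": rng.normal(size=10)}
        states = {"T": "gain"}
        for name in ["N1", "N2", "N3"]:
            profiles[name] = rng.normal(size=10)
            states[name] = "neutral"
        sub = _fake_subclone_set(profiles, states)
        outside = ~sub.cna.arm_gene_mask("1q")
        t = sub.profiles.loc["T"].to_numpy()[outside]
        expected = min(
            ["N1", "N2", "N3"],
            key=lambda c: np.linalg.norm(sub.profiles.loc[c].to_numpy()[outside] - t),
        )
        assert cna.match_closest_clone(sub, "T") == expected

    def test_equidistant_candidates_take_lower_label(self):
        sub = _fake_subclone_set(
            {"T": [1] * 5 + [0] * 5, "N2": [0] * 10, "N1": [0] * 10},
            {"T": "gain", "N1": "neutral", "N2": "neutral"},
        )
        assert cna.match_closest_clone(sub, "T") == "N1"

    def test_no_neutral_comparator_raises(self):
        sub = _fake_subclone_set(
            {"T": [1] * 10, "U": [1] * 10}, {"T": "gain", "U": "gain"}
        )
        with pytest.raises(ValueError, match="neutral comparator"):
            cna.match_closest_clone(sub, "T")


class TestCloneStability:
    def test_identity_is_one(self):
        assert cna.clone_stability_score({"A": 0.5, "B": 0.5}, {"A": 0.5, "B": 0.5}) == 1.0

    def test_crossed_fractions(self):
        score = cna.clone_stability_score({"A": 0.8, "B": 0.2}, {"A": 0.2, "B": 0.8})
        assert score == pytest.approx(0.25)

    def test_complete_turnover_is_zero(self):
        assert cna.clone_stability_score({"A": 1.0}, {"B": 1.0}) == 0.0

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            cna.clone_stability_score({"A": 0.0}, {"A": 0.0})

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.floats(0, 1, allow_nan=False), st.floats(0, 1, allow_nan=False)),
            min_size=1, max_size=6,
        ).filter(lambda ps: any(max(a, b) > 0 for a, b in ps))
    )
    def test_symmetry(self, pairs):
        pre = {f"c{i}": a for i, (a, _) in enumerate(pairs)}
        post = {f"c{i}": b for i, (_, b) in enumerate(pairs)}
        assert cna.clone_stability_score(pre, post) == pytest.approx(
            cna.clone_stability_score(post, pre)
        )
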