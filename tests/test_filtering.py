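"""Filter cascade: enrichment, censoring, and redundancy collapse."""

import random

import pytest

from perilipid.chem import C13_C12_DELTA, PROTON_MASS
from perilipid.filtering import (
    Feature,
    FilterConfig,
    MolecularEvent,
    collapse_adducts_dimers,
    collapse_isotopes,
    enrichment_filter,
    filter_pipeline,
    mass_defect_censor,
)
from perilipid.simulate import evaluate_filter_run, simulate_experiment


def feat(fid, mz, rt=10.0, sample=(1000.0,), control=(10.0,)):
    return Feature(fid, mz, rt, tuple(sample), tuple(control))


class TestEnrichment:
    def test_ratio_threshold_inclusive(self):
        kept, removed, ratios = enrichment_filter(
            [
                feat("a", 500.5, sample=(5000.0,) * 3, control=(400.0,) * 3),
                feat("b", 501.5, sample=(900.0,) * 3, control=(100.0,) * 3),
            ]
        )
        assert [f.feature_id for f in kept] == ["a"]
        assert ratios["a"] == pytest.approx(5000 / 401)
        assert ratios["b"] == pytest.approx(900 / 101)  # 8.91 < 10

    def test_zero_control_handled_by_pseudocount(self):
        kept, _, ratios = enrichment_filter(
            [feat("a", 500.5, sample=(500.0,), control=(0.0,))]
        )
        assert len(kept) == 1
        assert ratios["a"] == pytest.approx(500.0)

    def test_empty_intensities_rejected(self):
        with pytest.raises(ValueError):
            Feature("a", 500.0, 1.0, (), (1.0,))


class TestMassDefectCensor:
    def test_lipid_defect_kept(self):
        kept, censored, _ = mass_defect_censor([feat("a", 835.5361)])
        assert len(kept) == 1 and not censored

    def test_low_defect_censored(self):
        kept, censored, reasons = mass_defect_censor([feat("a", 412.051)])
        assert not kept
        assert reasons["a"] == "low_mass_defect"

    def test_salt_ladder_censored_regardless_of_defect(self):
        ladder = [
            feat("a", 400.00000, rt=1.0),
            feat("b", 467.98742, rt=1.0),
            feat("c", 535.97484, rt=1.0),
        ]
        kept, censored, reasons = mass_defect_censor(ladder)
        assert not kept
        assert len(censored) == 3

    def test_overlapping_ladders_fully_censored(self):
        # two ladders sharing rung positions must not mask each other
        rows = []
        for tag, base in (("x", 384.935213), ("y", 452.922633)):
            for k in range(4):
                rows.append(feat(f"{tag}{k}", base + k * 67.98742))
        kept, censored, _ = mass_defect_censor(rows)
        assert not kept and len(censored) == 8

    def test_out_of_range_passed_through(self):
        kept, censored, _ = mass_defect_censor([feat("a", 150.01), feat("b", 1700.02)])
        assert len(kept) == 2 and not censored

    def test_heavy_lipid_wrapped_defect_kept(self):
        # cardiolipin-scale ions have fractional mass wrapped past 1 Da
        kept, censored, _ = mass_defect_censor([feat("cl", 1394.0119)])
        assert len(kept) == 1


class TestIsotopeCollapse:
    def test_isotope_merges(self):
        events = collapse_isotopes(
            [
                feat("p", 835.5342, rt=12.00, sample=(1e6,) * 3),
                feat("i", 835.5342 + C13_C12_DELTA, rt=12.01, sample=(4.5e5,) * 3),
            ]
        )
        assert len(events) == 1
        assert events[0].representative.feature_id == "p"
        assert events[0].member_ids == ["i"]

    def test_rt_gate(self):
        events = collapse_isotopes(
            [
                feat("p", 835.5342, rt=12.00, sample=(1e6,) * 3),
                feat("i", 836.5376, rt=12.50, sample=(4.5e5,) * 3),
            ]
        )
        assert len(events) == 2

    def test_intensity_ceiling(self):
        events = collapse_isotopes(
            [
                feat("p", 835.5342, rt=12.00, sample=(1e6,) * 3),
                feat("i", 836.5376, rt=12.00, sample=(9e5,) * 3),
            ]
        )
        assert len(events) == 2  # ratio 0.9 exceeds the 0.6 ceiling

    def test_m2_chains_through_m1(self):
        events = collapse_isotopes(
            [
                feat("p", 835.5342, rt=12.0, sample=(1e6,)),
                feat("i1", 835.5342 + C13_C12_DELTA, rt=12.0, sample=(4.5e5,)),
                feat("i2", 835.5342 + 2 * C13_C12_DELTA, rt=12.0, sample=(1.2e5,)),
            ]
        )
        assert len(events) == 1
        assert set(events[0].member_ids) == {"i1", "i2"}


class TestAdductDimerCollapse:
    def test_formate_pair_merges_to_deprotonated(self):
        events = [
            MolecularEvent(feat("formate", 881.5397, rt=12.0, sample=(1e6,))),
            MolecularEvent(feat("deprot", 835.5342, rt=12.0, sample=(3e5,))),
        ]
        merged = collapse_adducts_dimers(events)
        assert len(merged) == 1
        assert merged[0].representative.feature_id == "deprot"
        assert merged[0].member_ids == ["formate"]

    def test_dimer_removed(self):
        events = [
            MolecularEvent(feat("p", 835.5342, rt=12.0, sample=(1e6,))),
            MolecularEvent(
                feat("d", 2 * 835.5342 + PROTON_MASS, rt=12.0, sample=(1e5,))
            ),
        ]
        merged = collapse_adducts_dimers(events)
        assert len(merged) == 1
        assert merged[0].provenance["d"] == "dimer"

    def test_dimer_of_alternate_adduct_member_removed(self):
        # the dimer was formed from the formate ion, which after adduct
        # collapse is only a member, not the representative
        events = [
            MolecularEvent(feat("formate", 881.5397, rt=12.0, sample=(1e6,))),
            MolecularEvent(feat("deprot", 835.5342, rt=12.0, sample=(3e5,))),
            MolecularEvent(
                feat("d", 2 * 881.5397 + PROTON_MASS, rt=12.0, sample=(1e5,))
            ),
        ]
        merged = collapse_adducts_dimers(events)
        assert len(merged) == 1

    def test_lone_feature_unchanged(self):
        events = [MolecularEvent(feat("p", 835.5342))]
        assert len(collapse_adducts_dimers(events)) == 1


# -- brute-force reference for the dedup stages ------------------------------


def brute_force_dedup(features, cfg=None):
    """Reference merger: recompute all candidate pairs at every step.

    Same merge semantics as the pipeline (greedy by descending intensity,
    ties by m/z then id) but written as a naive fixpoint over explicit
    all-pairs candidate scans.
    """
    cfg = cfg or FilterConfig()
    order = sorted(features, key=lambda f: (-f.mean_sample, f.mz, f.feature_id))
    events = []
    unassigned = list(order)
    while unassigned:
        rep = unassigned.pop(0)
        members = [rep]
        changed = True
        while changed:
            changed = False
            for cand in list(unassigned):
                for m in members:
                    iso = (
                        abs(cand.mz - m.mz - C13_C12_DELTA) <= cfg.mz_tol(cand.mz)
                        and abs(cand.rt - m.rt) <= cfg.rt_tol_min
                        and m.mean_sample > 0
                        and cand.mean_sample / m.mean_sample <= cfg.isotope_ratio_max
                    )
                    if iso:
                        members.append(cand)
                        unassigned.remove(cand)
                        changed = True
                        break
        events.append(members)
    # adduct pairing between event groups (by representative = members[0])
    merged = True
    while merged:
        merged = False
        events.sort(key=lambda ms: (-ms[0].mean_sample, ms[0].mz, ms[0].feature_id))
        for i in range(len(events)):
            for j in range(i + 1, len(events)):
                a, b = events[i][0], events[j][0]
                if abs(a.rt - b.rt) > cfg.rt_tol_min:
                    continue
                delta = abs(a.mz - b.mz)
                if any(
                    abs(delta - d) <= cfg.mz_tol(max(a.mz, b.mz))
                    for d in cfg.adduct_deltas
                ):
                    low, high = (i, j) if a.mz < b.mz else (j, i)
                    events[low].extend(events[high])
                    events[low].sort(
                        key=lambda f: (-f.mean_sample, f.mz, f.feature_id)
                    )
                    # canonical representative: lowest m/z form first
                    rep = min(events[low], key=lambda f: f.mz)
                    events[low].remove(rep)
                    events[low].insert(0, rep)
                    del events[high]
                    merged = True
                    break
            if merged:
                break
    # dimer removal against every member form
    removed = True
    while removed:
        removed = False
        for parent in events:
            targets = [2 * f.mz + PROTON_MASS for f in parent]
            for other in events:
                if other is parent:
                    continue
                if abs(other[0].rt - parent[0].rt) > cfg.rt_tol_min:
                    continue
                if any(
                    abs(other[0].mz - t) <= cfg.mz_tol(other[0].mz) for t in targets
                ):
                    parent.extend(other)
                    events.remove(other)
                    removed = True
                    break
            if removed:
                break
    return {frozenset(f.feature_id for f in ms) for ms in events}


def pipeline_dedup_partition(features, cfg=None):
    cfg = cfg or FilterConfig()
    events = collapse_adducts_dimers(collapse_isotopes(features, cfg), cfg)
    return {frozenset(e.all_ids) for e in events}


def random_instance(rng, n):
    """Small random mixtures of parents, isotopes, adducts, and dimers."""
    features = []
    i = 0
    while len(features) < n:
        base_mz = rng.uniform(300, 900)
        rt = rng.uniform(1, 19)
        inten = 10 ** rng.uniform(4, 6)
        i += 1
        features.append(feat(f"p{i}", base_mz, rt, (inten,), (1.0,)))
        for role, dm, frac in (
            ("iso", C13_C12_DELTA, rng.uniform(0.2, 0.8)),
            ("add", 46.005480, 0.3),
            ("dim", base_mz + PROTON_MASS, 0.1),
        ):
            if len(features) >= n or rng.random() > 0.5:
                continue
            features.append(
                feat(f"{role}{i}", base_mz + dm, rt, (inten * frac,), (1.0,))
            )
    return features[:n]


@pytest.mark.parametrize("seed", range(12))
def test_dedup_matches_brute_force(seed):
    rng = random.Random(seed)
    features = random_instance(rng, rng.randint(4, 20))
    assert pipeline_dedup_partition(features) == brute_force_dedup(features)


@pytest.mark.parametrize("seed", [0, 3])
def test_order_invariance(seed):
    rng = random.Random(seed)
    features = random_instance(rng, 15)
    baseline = pipeline_dedup_partition(features)
    for _ in range(5):
        rng.shuffle(features)
        assert pipeline_dedup_partition(features) == baseline


class TestPipeline:
    def test_empty_input(self):
        events, audit = filter_pipeline([])
        assert events == []
        assert audit.as_dict() == {
            "input": 0,
            "enriched": 0,
            "after_censor": 0,
            "after_dedup": 0,
        }

    def test_audit_monotone_and_conserving(self):
        features, _ = simulate_experiment(3, 30)
        cfg = FilterConfig()
        events, audit = filter_pipeline(features, cfg)
        counts = list(audit.as_dict().values())
        assert counts == sorted(counts, reverse=True)
        # stage conservation
        kept, removed, _ = enrichment_filter(features, cfg)
        assert len(kept) + len(removed) == len(features)
        kept2, censored, _ = mass_defect_censor(kept, cfg)
        assert len(kept2) + len(censored) == len(kept)
        # dedup conserves features inside events
        n_collapsed = sum(len(e.all_ids) for e in events)
        assert n_collapsed <= len(kept2)

    def test_synthetic_recovery_single_seed(self):
        features, truth = simulate_experiment(1, 50)
        events, _ = filter_pipeline(features)
        metrics = evaluate_filter_run(events, truth)
        assert metrics["sensitivity"] >= 0.95
        assert metrics["artifact_leakage"] <= 0.05
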