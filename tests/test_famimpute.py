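"""Family engine: subsets, Mendelian screen, transmission, imputation."""

import itertools

import networkx as nx
import numpy as np
import pytest

from pedimpute.core import (
    MISSING,
    GeneticMap,
    GenotypeMatrix,
    HaplotypePanel,
    Individual,
    Pedigree,
    Variant,
)
from pedimpute.famimpute import (
    TransmissionSegments,
    detect_mendelian_errors,
    impute_family,
    infer_transmission,
    select_family_subset,
)
from pedimpute.pedsim import SimConfig, simulate_pedigrees, simulate_study
from tests.conftest import make_matrix


def three_generations() -> Pedigree:
    """gpa/gma -> dad (+ mom) -> me (+ wife) -> son -> grandkid."""
    return Pedigree("F", [
        Individual("ggpa", sex=1), Individual("ggma", sex=2),
        Individual("gpa", father="ggpa", mother="ggma", sex=1),
        Individual("gma", sex=2),
        Individual("dad", father="gpa", mother="gma", sex=1),
        Individual("mom", sex=2),
        Individual("me", father="dad", mother="mom", sex=1),
        Individual("sis", father="dad", mother="mom", sex=2),
        Individual("wife", sex=2),
        Individual("son", father="me", mother="wife", sex=1),
        Individual("dil", sex=2),
        Individual("grandkid", father="son", mother="dil", sex=1),
    ])


class TestFamilySubset:
    def test_masked_founder_gets_nuclear_family_only(self):
        ped = Pedigree("F", [
            Individual("a", sex=1), Individual("b", sex=2),
            Individual("c", father="a", mother="b", sex=1),
        ])
        subset = select_family_subset(ped, "a")
        assert set(subset.members) == {"a", "b", "c"}

    def test_three_generation_rule_reading(self):
        subset = select_family_subset(three_generations(), "me")
        want = {"me", "dad", "mom", "sis", "wife", "son",  # nuclear
                "gpa", "gma",                              # grandparents
                "grandkid"}                                # grandchildren
        assert set(subset.members) == want  # great-grandparents excluded

    def test_absent_id_is_an_error(self):
        with pytest.raises(KeyError):
            select_family_subset(three_generations(), "nobody")

    def test_matches_independent_graph_walk_on_simulated_families(self):
        peds = simulate_pedigrees(SimConfig(n_families=25, seed=21))
        for ped in peds:
            g = nx.DiGraph()
            for ind in ped.members.values():
                g.add_node(ind.iid)
                if ind.father:
                    g.add_edge(ind.father, ind.iid)
                    g.add_edge(ind.mother, ind.iid)
            for masked in ped.members:
                parents = set(g.predecessors(masked))
                children = set(g.successors(masked))
                sibs = {
                    s for p in parents for s in g.successors(p)
                    if s != masked and set(g.predecessors(s)) == parents
                }
                spouses = {
                    q for c in children for q in g.predecessors(c)
                } - {masked}
                grandparents = {gp for p in parents for gp in g.predecessors(p)}
                grandchildren = {gc for c in children for gc in g.successors(c)}
                want = ({masked} | parents | children | sibs | spouses
                        | grandparents | grandchildren)
                got = set(select_family_subset(ped, masked).members)
                assert got == want, masked


class TestMendelianErrors:
    def trio(self):
        return Pedigree("T", [
            Individual("f", sex=1), Individual("m", sex=2),
            Individual("c", father="f", mother="m"),
        ])

    @pytest.mark.parametrize("gf,gm,gc,flagged", [
        (0, 0, 1, True),    # parents both hom-ref, child carries alt
        (0, 0, 2, True),
        (2, 0, 1, False),   # obligate het: consistent
        (2, 0, 0, True),
        (2, 2, 1, True),
        (1, 1, 2, False),
        (MISSING, 0, 2, True),   # even one missing parent can contradict
        (MISSING, MISSING, 2, False),
        (0, MISSING, MISSING, False),  # missing child never flags
    ])
    def test_trio_rule(self, gf, gm, gc, flagged):
        g = make_matrix([[gf], [gm], [gc]], ids=["f", "m", "c"])
        flags = detect_mendelian_errors(g, self.trio())
        assert (len(flags) == 1) == flagged

    def test_planted_inconsistencies_recovered_exactly(self):
        study = simulate_study(SimConfig(
            n_families=6, n_sequence_variants=300, n_gwas_variants=40,
            n_reference=10, seed=31, variant_missing_rate=0.02,
            individual_missing_rate=0.0, fraction_both=1.0,
            fraction_gwas_only=0.0, fraction_seq_only=0.0,
        ))
        seq = study.sequence.copy()
        ped = study.pedigrees[0]
        trio_child = next(i for i in ped.nonfounders())
        f, m = ped.parents_of(trio_child)
        rows = [seq.individuals.index(i) for i in (f, m, trio_child)]
        rng = np.random.default_rng(5)
        planted = sorted(rng.choice(seq.n_variants, size=50, replace=False))
        for j in planted:
            seq.calls[rows[0], j] = 0
            seq.calls[rows[1], j] = 0
            seq.calls[rows[2], j] = 2
        flags = set()
        for fam in study.pedigrees:
            flags |= detect_mendelian_errors(seq, fam)
        assert flags == {seq.variants[j].vid for j in planted}


# ---------------------------------------------------------------------------
# transmission


def duo_inputs(parent_h0, parent_h1, child_calls, other_calls=None,
               length_cm=0.5):
    """Trio scaffold (f, m, c) with f's phase given; returns the pieces."""
    M = len(parent_h0)
    positions = [10_000 * (j + 1) for j in range(M)]
    variants = [Variant(f"s{j}", positions[j]) for j in range(M)]
    other = other_calls if other_calls is not None else [0] * M
    parent_calls = (np.array(parent_h0) + np.array(parent_h1)).tolist()
    scaffold = GenotypeMatrix(
        ["f", "m", "c"], variants,
        np.array([parent_calls, other, child_calls], dtype=np.int8),
    )
    haps = np.zeros((6, M), dtype=np.int8)
    haps[0], haps[1] = parent_h0, parent_h1
    oh = np.array(other, dtype=np.int8)
    haps[2], haps[3] = np.minimum(oh, 1), np.maximum(oh - 1, 0)
    phase = HaplotypePanel(
        variants, haps,
        [("f", 0), ("f", 1), ("m", 0), ("m", 1), ("c", 0), ("c", 1)],
    )
    ped = Pedigree("T", [
        Individual("f", sex=1), Individual("m", sex=2),
        Individual("c", father="f", mother="m"),
    ])
    gmap = GeneticMap([1, positions[-1] + 1], [0.0, length_cm])
    subset = select_family_subset(ped, "c")
    return subset, scaffold, gmap, phase, ped


def oracle_chain(emit, switch):
    """Exhaustive 2-state path enumeration."""
    M = emit.shape[1]
    p0 = np.zeros(M)
    total = 0.0
    for path in itertools.product((0, 1), repeat=M):
        w = 0.5
        for t in range(1, M):
            w *= switch[t - 1] if path[t] != path[t - 1] else 1 - switch[t - 1]
        for t in range(M):
            w *= emit[path[t], t]
        total += w
        for t in range(M):
            if path[t] == 0:
                p0[t] += w
    return p0 / total


class TestInferTransmission:
    def test_homozygous_parent_gives_exactly_half(self):
        subset, scaffold, gmap, phase, ped = duo_inputs(
            [1, 1, 1, 1], [1, 1, 1, 1], [1, 1, 1, 1]
        )
        segs = infer_transmission(subset, scaffold, gmap, phase, ped)
        assert np.allclose(segs[("c", 0)].p_hap0, 0.5)

    def test_fully_informative_meiosis_is_confident(self):
        # father het everywhere, child always carries hap0's allele
        h0 = [1, 0, 1, 0, 1, 0, 1, 0]
        h1 = [0, 1, 0, 1, 0, 1, 0, 1]
        child = list(h0)  # mother contributes ref everywhere
        subset, scaffold, gmap, phase, ped = duo_inputs(h0, h1, child,
                                                        length_cm=0.1)
        segs = infer_transmission(subset, scaffold, gmap, phase, ped)
        assert np.all(segs[("c", 0)].p_hap0 > 0.99)

    def test_missing_parent_genotypes_mean_uninformative(self):
        subset, scaffold, gmap, phase, ped = duo_inputs(
            [1, 0, 1], [0, 1, 0], [1, 0, 1]
        )
        scaffold.calls[0, :] = MISSING  # father's observed calls gone
        segs = infer_transmission(subset, scaffold, gmap, phase, ped)
        assert np.allclose(segs[("c", 0)].p_hap0, 0.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_two_state_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        M = int(rng.integers(3, 9))
        h0 = rng.integers(0, 2, size=M)
        h1 = rng.integers(0, 2, size=M)
        other = rng.integers(0, 3, size=M).tolist()
        # child = random transmission + allele from the other parent
        src = rng.integers(0, 2, size=M)
        from_f = np.where(src == 0, h0, h1)
        from_m = np.array([rng.integers(0, 2) if o == 1 else o // 2
                           for o in other])
        child = (from_f + from_m).tolist()
        subset, scaffold, gmap, phase, ped = duo_inputs(
            h0.tolist(), h1.tolist(), child, other_calls=other,
            length_cm=float(rng.uniform(0.1, 3.0)),
        )
        segs = infer_transmission(subset, scaffold, gmap, phase, ped)
        # independent oracle from the same model definition
        cm = np.asarray(gmap.cm_at(scaffold.positions), dtype=float)
        switch = 0.5 * (1 - np.exp(-2 * np.diff(cm) / 100))
        t_other = np.array([0.5 if o == 1 else o / 2 for o in other])
        emit = np.ones((2, M))
        for st, hap in ((0, h0), (1, h1)):
            need = np.array(child) - hap
            emit[st] = np.where(need == 0, 1 - t_other,
                                np.where(need == 1, t_other, 0.0))
        dead = emit.sum(axis=0) == 0
        emit[:, dead] = 1.0
        want = oracle_chain(emit, switch)
        assert np.allclose(segs[("c", 0)].p_hap0, want, atol=1e-10)

    def test_segments_tile_region_without_overlap(self):
        subset, scaffold, gmap, phase, ped = duo_inputs(
            [1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0]
        )
        segs = infer_transmission(subset, scaffold, gmap, phase, ped)
        ivals = segs[("c", 0)].intervals()
        assert ivals[0][0] == gmap.bp[0] and ivals[-1][1] == gmap.bp[-1]
        for a, b in zip(ivals, ivals[1:]):
            assert a[1] == b[0]
        assert all(0.0 <= iv[3] <= 1.0 for iv in ivals)


# ---------------------------------------------------------------------------
# dense imputation


def nuclear(n_children=3) -> Pedigree:
    kids = [Individual(f"c{k}", father="f", mother="m") for k in range(n_children)]
    return Pedigree("N", [Individual("f", sex=1), Individual("m", sex=2), *kids])


def const_segs(ped, weights: dict, positions) -> dict:
    """Constant-weight TransmissionSegments for every meiosis."""
    out = {}
    region = (0, int(positions[-1]) + 10)
    for (child, k), w in weights.items():
        out[(child, k)] = TransmissionSegments(
            child, k, np.asarray(positions),
            np.full(len(positions), float(w)), region,
        )
    return out


class TestImputeFamily:
    def test_hom_ref_parents_force_hom_ref_child(self):
        ped = nuclear(1)
        dense = make_matrix([[0, 0], [0, 0]], ids=["f", "m"])
        subset = select_family_subset(ped, "c0")
        segs = const_segs(ped, {("c0", 0): 1.0, ("c0", 1): 1.0},
                          [100, 200])
        gp = impute_family(subset, dense, segs, "c0", ped)
        assert np.allclose(gp.row("c0"), [[1, 0, 0], [1, 0, 0]], atol=1e-12)

    def test_uninformative_family_falls_back_to_hardy_weinberg(self):
        ped = nuclear(1)
        # subset members have no data; unrelated panel rows set the freq
        dense = make_matrix(
            [[MISSING], [MISSING], [1], [2]], ids=["f", "m", "x1", "x2"]
        )
        subset = select_family_subset(ped, "c0")
        segs = {}
        gp = impute_family(subset, dense, segs, "c0", ped)
        f = 3 / 4  # panel-wide alt frequency: calls {1, 2} = 3 of 4 alleles
        want = [(1 - f) ** 2, 2 * f * (1 - f), f ** 2]
        assert np.allclose(gp.row("c0")[0], want, atol=1e-12)
        assert gp.low_confidence[0]

    def test_observed_scaffold_call_overrides_posterior(self):
        ped = nuclear(1)
        dense = make_matrix([[0], [0]], ids=["f", "m"])
        subset = select_family_subset(ped, "c0")
        obs = make_matrix([[2]], ids=["c0"])
        gp = impute_family(subset, dense, {}, "c0", ped, observed_calls=obs)
        assert np.allclose(gp.row("c0")[0], [0, 0, 1])

    def test_posteriors_always_normalised(self):
        ped = three_generations()
        rng = np.random.default_rng(2)
        ids = list(ped.members)
        calls = rng.integers(0, 3, size=(len(ids), 30)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.3] = MISSING
        dense = make_matrix(calls, ids=ids)
        subset = select_family_subset(ped, "me")
        positions = dense.positions
        weights = {}
        for iid in ids:
            if ped.parents_of(iid):
                weights[(iid, 0)] = rng.random()
                weights[(iid, 1)] = rng.random()
        segs = const_segs(ped, weights, positions)
        gp = impute_family(subset, dense.subset([i for i in ids if i != "me"], None),
                           segs, "me", ped)
        assert np.allclose(gp.probs.sum(axis=2), 1.0, atol=1e-9)
        assert np.all(gp.probs >= 0)

    def test_invariant_to_relative_listing_order(self):
        ped = nuclear(3)
        rng = np.random.default_rng(7)
        ids = ["f", "m", "c1", "c2"]
        calls = rng.integers(0, 3, size=(4, 12)).astype(np.int8)
        dense_a = make_matrix(calls, ids=ids)
        order = [2, 0, 3, 1]
        dense_b = dense_a.subset([ids[i] for i in order], None)
        subset = select_family_subset(ped, "c0")
        weights = {(f"c{k}", j): rng.random() for k in range(3) for j in (0, 1)}
        segs = const_segs(ped, weights, dense_a.positions)
        a = impute_family(subset, dense_a, segs, "c0", ped)
        b = impute_family(subset, dense_b, segs, "c0", ped)
        assert np.allclose(a.probs, b.probs, atol=1e-12)

    def test_inbred_pedigree_rejected(self):
        ped = Pedigree("L", [
            Individual("f", sex=1), Individual("m", sex=2),
            Individual("s", father="f", mother="m", sex=1),
            Individual("d", father="f", mother="m", sex=2),
            Individual("x", father="s", mother="d"),
        ])
        dense = make_matrix([[0]], ids=["f"])
        subset = select_family_subset(ped, "x")
        with pytest.raises(ValueError, match="looped|inbred"):
            impute_family(subset, dense, {}, "x", ped)

    @pytest.mark.parametrize("seed", range(6))
    def test_nuclear_family_matches_exhaustive_enumeration(self, seed):
        """5-member nuclear family vs. brute-force enumeration of all
        parent-haplotype configurations and transmissions, weighted by
        segment posteriors."""
        rng = np.random.default_rng(seed)
        V = 10
        ped = nuclear(3)  # f, m, c0 (masked), c1, c2
        gf = rng.integers(0, 3, size=V)
        gm = rng.integers(0, 3, size=V)
        # sibling genotypes drawn consistently with the parents
        def draw_child():
            af = np.array([rng.integers(0, 2) if g == 1 else g // 2 for g in gf])
            am = np.array([rng.integers(0, 2) if g == 1 else g // 2 for g in gm])
            return af + am
        calls = np.stack([gf, gm, draw_child(), draw_child()]).astype(np.int8)
        dense = make_matrix(calls, ids=["f", "m", "c1", "c2"])
        subset = select_family_subset(ped, "c0")
        weights = {(f"c{k}", j): float(rng.random())
                   for k in range(3) for j in (0, 1)}
        segs = const_segs(ped, weights, dense.positions)
        got = impute_family(subset, dense, segs, "c0", ped,
                            mode="agnostic").row("c0")

        # oracle: exhaustive sum over parents' ordered haplotype pairs and
        # all per-child transmissions
        def pair_options(g):
            if g == 0:
                return [((0, 0), 1.0)]
            if g == 2:
                return [((1, 1), 1.0)]
            return [((0, 1), 0.5), ((1, 0), 0.5)]

        want = np.zeros((V, 3))
        for v in range(V):
            dist = np.zeros(3)
            for (hf, pf) in pair_options(int(gf[v])):
                for (hm, pm) in pair_options(int(gm[v])):
                    # sibling likelihoods
                    like = pf * pm
                    for sib in ("c1", "c2"):
                        wf = weights[(sib, 0)]
                        wm = weights[(sib, 1)]
                        tf = wf * hf[0] + (1 - wf) * hf[1]
                        tm = wm * hm[0] + (1 - wm) * hm[1]
                        gs = int(dense.row(sib)[v])
                        p = [
                            (1 - tf) * (1 - tm),
                            tf * (1 - tm) + (1 - tf) * tm,
                            tf * tm,
                        ][gs]
                        like *= p
                    wf0 = weights[("c0", 0)]
                    wm0 = weights[("c0", 1)]
                    tf = wf0 * hf[0] + (1 - wf0) * hf[1]
                    tm = wm0 * hm[0] + (1 - wm0) * hm[1]
                    dist[0] += like * (1 - tf) * (1 - tm)
                    dist[1] += like * (tf * (1 - tm) + (1 - tf) * tm)
                    dist[2] += like * tf * tm
            want[v] = dist / dist.sum()
        assert np.allclose(got, want, atol=1e-8)
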