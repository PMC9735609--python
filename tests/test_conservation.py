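"""Conservation set algebra, clusters, and chromosome summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from imprintcall import (
    assign_sets,
    find_clusters,
    interspecies_join,
    overlap_groups,
    summarize_chromosomes,
)
from imprintcall.calling import UNTESTABLE as UNTESTABLE_STATUS
from imprintcall.conservation import (
    CONSERVED,
    IMPRINTED,
    NON_CONSERVED,
    NOT_IMPRINTED,
    UNCLASSIFIED,
)

MO17_PAIRS = ("BM-C/C-BM", "MB-C/C-MB", "BC/CB")
B73_PAIRS = ("BM-C/C-BM", "MB-C/C-MB", "MC/CM")


def status_map(gene_states, pairs=MO17_PAIRS):
    """gene -> (s1, s2, s_ref) into the pair->gene->status mapping."""
    out = {p: {} for p in pairs}
    for gene, states in gene_states.items():
        for pair, state in zip(pairs, states):
            out[pair][gene] = state
    return out


I, N, U = IMPRINTED, NOT_IMPRINTED, UNTESTABLE_STATUS


class TestAssignSets:
    def test_imprinted_in_hybrids_only_is_non_conserved(self):
        # imprinted in BM-C/C-BM and MB-C/C-MB, not in BC/CB -> sets {I, IV}
        [a] = assign_sets(status_map({"g": (I, I, N)}), "Mo17-added")
        assert a.sets == frozenset({"I", "IV"})
        assert a.label == NON_CONSERVED

    def test_imprinted_everywhere_is_conserved(self):
        [a] = assign_sets(status_map({"g": (I, I, I)}), "Mo17-added")
        assert a.sets == frozenset({"III", "VI"})
        assert a.label == CONSERVED

    def test_imprinted_nowhere_is_unclassified(self):
        [a] = assign_sets(status_map({"g": (N, N, N)}), "Mo17-added")
        assert a.sets == frozenset()
        assert a.label == UNCLASSIFIED

    def test_untestable_anywhere_excludes_from_set_logic(self):
        [a] = assign_sets(status_map({"g": (I, I, U)}), "Mo17-added")
        assert a.sets == frozenset()
        assert a.label == UNCLASSIFIED

    def test_missing_pair_errors_by_name(self):
        with pytest.raises(ValueError, match="BC/CB"):
            assign_sets({"BM-C/C-BM": {}, "MB-C/C-MB": {}}, "Mo17-added")

    @pytest.mark.parametrize(
        "group,pairs,labels",
        [
            ("Mo17-added", MO17_PAIRS, (("I", "II", "III"), ("IV", "V", "VI"))),
            ("B73-added", B73_PAIRS, (("VII", "VIII", "IX"), ("X", "XI", "XII"))),
        ],
    )
    def test_exhaustive_combinations_match_enumerated_oracle(self, group, pairs, labels):
        """All 8 testable imprinted/not combinations across the three pairs
        reproduce the hand-enumerated set memberships, for both groups."""
        for t1, t2, r in itertools.product([True, False], repeat=3):
            states = (I if t1 else N, I if t2 else N, I if r else N)
            [a] = assign_sets(status_map({"g": states}, pairs), group)
            want = set()
            for (only_t, only_r, both), t in zip(labels, (t1, t2)):
                if t and not r:
                    want.add(only_t)
                elif r and not t:
                    want.add(only_r)
                elif t and r:
                    want.add(both)
            assert a.sets == frozenset(want)
            # mutual exclusivity within each comparison
            assert not ({labels[0][0], labels[0][1]} <= a.sets)
            assert not ({labels[1][0], labels[1][1]} <= a.sets)
            if t1 and t2 and r:
                assert a.label == CONSERVED
            elif (t1 != r) and (t2 != r):
                assert a.label == NON_CONSERVED
            else:
                assert a.label == UNCLASSIFIED

    def test_conserved_and_non_conserved_disjoint(self):
        states = {
            f"g{i}": combo
            for i, combo in enumerate(itertools.product([I, N, U], repeat=3))
        }
        out = assign_sets(status_map(states), "Mo17-added")
        conserved = {a.gene_id for a in out if a.label == CONSERVED}
        non_conserved = {a.gene_id for a in out if a.label == NON_CONSERVED}
        assert not conserved & non_conserved


class TestOverlapGroups:
    def _assignments(self, genes, label, group):
        return assign_sets(
            status_map(
                {g: (I, I, I) if label == CONSERVED else (I, I, N) for g in genes},
                MO17_PAIRS if group == "Mo17-added" else B73_PAIRS,
            ),
            group,
        )

    def test_disjoint_lists_overlap_zero(self):
        a = self._assignments(["a", "b"], CONSERVED, "Mo17-added")
        b = self._assignments(["c", "d"], CONSERVED, "B73-added")
        assert overlap_groups(a, b)[CONSERVED]["n_overlap"] == 0

    def test_identical_lists_overlap_fully(self):
        a = self._assignments(["a", "b", "c"], CONSERVED, "Mo17-added")
        b = self._assignments(["a", "b", "c"], CONSERVED, "B73-added")
        rep = overlap_groups(a, b)[CONSERVED]
        assert rep["n_overlap"] == 3 and rep["fraction_of_a"] == 1.0

    def test_partial_intersection(self):
        a = self._assignments(["a", "b", "c"], NON_CONSERVED, "Mo17-added")
        b = self._assignments(["b", "c", "d"], NON_CONSERVED, "B73-added")
        assert overlap_groups(a, b)[NON_CONSERVED]["overlap"] == ["b", "c"]


class TestInterspeciesJoin:
    def _assignments(self):
        genes = [f"g{i}" for i in range(10)]
        return assign_sets(status_map({g: (I, I, I) for g in genes}), "Mo17-added")

    def test_empty_table_gives_empty_rates(self):
        _, rates = interspecies_join(self._assignments(), pd.DataFrame())
        assert rates.empty

    def test_half_imprinted_gives_fifty_percent(self):
        tab = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(10)],
                "species": "rice",
                "ortholog_id": [f"Os{i}" for i in range(10)],
                "imprinted": [i < 5 for i in range(10)],
            }
        )
        _, rates = interspecies_join(self._assignments(), tab)
        assert rates.set_index("species").loc["rice", "rate"] == 0.5

    def test_multi_species_flags_counted_per_species(self):
        tab = pd.DataFrame(
            {
                "gene_id": ["g0", "g0"],
                "species": ["rice", "sorghum"],
                "ortholog_id": ["OsX", "SbX"],
                "imprinted": [True, True],
            }
        )
        per_gene, rates = interspecies_join(self._assignments(), tab)
        assert len(per_gene) == 2
        assert set(rates["species"]) == {"rice", "sorghum"}
        assert (rates["rate"] == 1.0).all()

    def test_unknown_genes_excluded_from_denominator(self):
        tab = pd.DataFrame(
            {
                "gene_id": ["g0", "nope"],
                "species": ["rice", "rice"],
                "ortholog_id": ["a", "b"],
                "imprinted": [True, True],
            }
        )
        _, rates = interspecies_join(self._assignments(), tab)
        assert rates.set_index("species").loc["rice", "n_genes"] == 1


def gene_table(positions, chrom="chr1", length=1000):
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(positions))],
            "chrom": chrom,
            "start": positions,
            "end": [p + length for p in positions],
        }
    )


def brute_force_clusters(positions, window):
    """O(n^2) chaining oracle: sort anchors, link consecutive gaps <= window."""
    order = np.argsort(positions, kind="stable")
    chains, chain = [], [order[0]] if len(positions) else []
    for i, j in zip(order[:-1], order[1:]):
        if positions[j] - positions[i] <= window:
            chain.append(j)
        else:
            chains.append(chain)
            chain = [j]
    if chain:
        chains.append(chain)
    return [sorted(c) for c in chains if len(c) >= 2]


class TestFindClusters:
    def test_genes_800kb_apart_form_one_cluster(self):
        out = find_clusters(gene_table([100_000, 900_000]))
        assert len(out) == 1 and len(out[0].member_gene_ids) == 2

    def test_genes_beyond_window_do_not_cluster(self):
        assert find_clusters(gene_table([100_000, 1_300_000])) == []

    def test_chained_triple_spans_beyond_one_window(self):
        out = find_clusters(gene_table([100_000, 900_000, 1_700_000]))
        assert len(out) == 1
        assert out[0].member_gene_ids == ("g0", "g1", "g2")

    def test_chromosomes_never_mix(self):
        genes = pd.concat(
            [gene_table([100, 200]), gene_table([150, 250], chrom="chr2")],
            ignore_index=True,
        )
        genes["gene_id"] = [f"g{i}" for i in range(4)]
        out = find_clusters(genes)
        assert {c.chrom for c in out} == {"chr1", "chr2"}

    def test_missing_coordinates_rejected(self):
        genes = gene_table([100, 200])
        genes.loc[0, "start"] = np.nan
        with pytest.raises(ValueError):
            find_clusters(genes)

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(2, 50))
            positions = sorted(int(p) for p in rng.integers(1, 10_000_000, size=n))
            positions = list(dict.fromkeys(positions))
            genes = gene_table(positions, length=10)
            got = find_clusters(genes, window=1_000_000)
            want = brute_force_clusters(positions, 1_000_000)
            got_members = [list(c.member_gene_ids) for c in got]
            want_members = [[f"g{i}" for i in c] for c in want]
            assert got_members == want_members

    def test_membership_invariant_under_shuffling(self):
        rng = np.random.default_rng(3)
        positions = sorted(int(p) for p in rng.integers(1, 5_000_000, size=30))
        genes = gene_table(positions, length=10)
        shuffled = genes.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = [c.member_gene_ids for c in find_clusters(genes)]
        b = [c.member_gene_ids for c in find_clusters(shuffled)]
        assert sorted(a) == sorted(b)


class TestSummarizeChromosomes:
    def _calls(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "cross_pair", "tissue", "status"])

    def test_all_on_one_chromosome(self):
        calls = self._calls(
            [("g0", "p", "embryo", "MEG"), ("g1", "p", "embryo", "PEG")]
        )
        models = gene_table([100, 200])
        out = summarize_chromosomes(calls, models)
        assert out["per_chromosome"]["chr1"]["embryo"] == 2

    def test_empty_calls_all_zero(self):
        calls = self._calls([])
        out = summarize_chromosomes(calls, gene_table([100]))
        assert out["per_chromosome"]["chr1"] == {"embryo": 0, "endosperm": 0}

    def test_tissue_overlap_listed(self):
        calls = self._calls(
            [
                ("g0", "p", "embryo", "MEG"),
                ("g0", "p", "endosperm", "MEG"),
                ("g1", "p", "endosperm", "PEG"),
            ]
        )
        out = summarize_chromosomes(calls, gene_table([100, 200]))
        assert out["embryo_endosperm_overlap"] == ["g0"]

    def test_synthetic_truth_placement_matches_manifest(self, small_study):
        from imprintcall import call_all

        calls = call_all(small_study.gene_counts, small_study.design)
        models = small_study.truth.reset_index()[["gene_id", "chrom", "start", "end"]]
        out = summarize_chromosomes(calls, models)
        total = sum(v["endosperm"] for v in out["per_chromosome"].values())
        imprinted_genes = set(
            calls.loc[
                (calls["tissue"] == "endosperm") & calls["status"].isin(["MEG", "PEG"]),
                "gene_id",
            ]
        )
        assert total == len(imprinted_genes)
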