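"""Orthogroup clustering, core selection, shared-presence matrix."""

import numpy as np
import pytest

from erosym.orthology import (
    OrthogroupTable,
    cluster_orthogroups,
    protein_identity,
    select_core,
    shared_matrix,
)

AA = list("ACDEFGHIKLMNPQRSTVWY")


def random_protein(rng, length=80):
    return "".join(rng.choice(AA, size=length))


def mutate_protein(rng, seq, frac):
    out = list(seq)
    for i in np.where(rng.random(len(seq)) < frac)[0]:
        out[i] = rng.choice(AA)
    return "".join(out)


def brute_force_components(proteomes, min_identity=0.5, min_coverage=0.5):
    """Independent oracle: all-pairs predicate + hand-written BFS."""
    nodes = sorted(
        (gid, gene, seq) for gid, prot in proteomes.items() for gene, seq in prot.items()
    )
    n = len(nodes)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = nodes[i][2], nodes[j][2]
            longer = max(len(a), len(b))
            # naive Needleman–Wunsch unit-cost edit distance
            import itertools

            prev = list(range(len(b) + 1))
            for x, ca in enumerate(a, 1):
                cur = [x] + [0] * len(b)
                for y, cb in enumerate(b, 1):
                    cur[y] = min(prev[y] + 1, cur[y - 1] + 1, prev[y - 1] + (ca != cb))
                prev = cur
            ident = (longer - prev[-1]) / longer
            cov = min(len(a), len(b)) / longer
            if ident >= min_identity and cov >= min_coverage:
                adj[i].add(j)
                adj[j].add(i)
    seen, comps = set(), []
    for s in range(n):
        if s in seen:
            continue
        stack, comp = [s], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj[u] - comp)
        seen |= comp
        comps.append(frozenset((nodes[i][0], nodes[i][1]) for i in comp))
    return set(comps)


def table_components(table: OrthogroupTable):
    return {
        frozenset(
            (gid, gene) for gid, genes in by_genome.items() for gene in genes
        )
        for by_genome in table.members.values()
    }


class TestClustering:
    def test_identical_proteomes(self, rng):
        prots = {f"p{i}": random_protein(rng) for i in range(10)}
        table = cluster_orthogroups({"gA": dict(prots), "gB": dict(prots)})
        assert len(table.members) == 10
        for og in table.members:
            assert table.single_copy(og) and table.prevalence(og) == 1.0

    def test_duplicated_gene_breaks_single_copy(self, rng):
        p = random_protein(rng)
        table = cluster_orthogroups(
            {"gA": {"x": p, "x2": p}, "gB": {"y": p}}
        )
        og = next(iter(table.members))
        assert len(table.genes_of(og)) == 3
        assert not table.single_copy(og)

    def test_matches_brute_force_on_planted_clusters(self, rng):
        # 5 planted clusters at ~90% identity; inter-cluster is random (~5%)
        proteomes = {"gA": {}, "gB": {}, "gC": {}}
        for c in range(5):
            seed_prot = random_protein(rng, 90)
            for gid in proteomes:
                for k in range(2 if gid == "gA" else 1):
                    proteomes[gid][f"c{c}_{gid}{k}"] = mutate_protein(rng, seed_prot, 0.1)
        table = cluster_orthogroups(proteomes)
        assert len(table.members) == 5
        assert table_components(table) == brute_force_components(proteomes)

    def test_prefilter_equals_exhaustive(self, rng):
        proteomes = {"gA": {}, "gB": {}}
        for c in range(6):
            p = random_protein(rng, 60)
            proteomes["gA"][f"a{c}"] = p
            proteomes["gB"][f"b{c}"] = mutate_protein(rng, p, 0.2)
        t1 = cluster_orthogroups(proteomes, prefilter=True)
        t2 = cluster_orthogroups(proteomes, prefilter=False)
        assert table_components(t1) == table_components(t2)

    def test_permutation_invariance(self, rng):
        proteomes = {
            f"g{i}": {f"g{i}_p{j}": random_protein(rng, 50) for j in range(5)}
            for i in range(3)
        }
        shuffled = {k: dict(reversed(list(v.items()))) for k, v in reversed(list(proteomes.items()))}
        assert table_components(cluster_orthogroups(proteomes)) == table_components(
            cluster_orthogroups(shuffled)
        )

    def test_empty_proteome_rejected(self, rng):
        with pytest.raises(ValueError, match="empty proteome"):
            cluster_orthogroups({"gA": {"x": "ACDEF"}, "gB": {}})

    def test_identity_definition(self):
        ident, cov = protein_identity("AAAA", "AAAA")
        assert (ident, cov) == (1.0, 1.0)
        ident, cov = protein_identity("AAAAAAAA", "AAAA")
        assert cov == 0.5 and ident == 0.5


def toy_table():
    members = {}
    # og present in 13 of 14 genomes, single copy
    members["OG000001"] = {f"g{i:02d}": [f"g{i:02d}_a"] for i in range(13)}
    # universal og
    members["OG000002"] = {f"g{i:02d}": [f"g{i:02d}_b"] for i in range(14)}
    # universal but multi-copy in one genome
    members["OG000003"] = {
        f"g{i:02d}": [f"g{i:02d}_c"] if i else ["g00_c", "g00_c2"] for i in range(14)
    }
    return OrthogroupTable(members, n_genomes=14, genome_ids=[f"g{i:02d}" for i in range(14)])


class TestCoreSelection:
    def test_threshold_arithmetic_13_of_14(self):
        t = toy_table()
        assert "OG000001" in select_core(t, 0.90, single_copy_only=True)
        assert "OG000001" not in select_core(t, 0.95, single_copy_only=True)

    def test_single_copy_filter(self):
        assert "OG000003" not in select_core(toy_table(), 0.60)

    def test_nested_cores(self):
        t = toy_table()
        cores = [select_core(t, thr) for thr in (0.95, 0.90, 0.80, 0.70, 0.60)]
        for small, big in zip(cores, cores[1:]):
            assert small <= big

    def test_exclusion_removes_exactly_its_orthogroup(self):
        t = toy_table()
        base = select_core(t, 0.60)
        reduced = select_core(t, 0.60, exclude_gene_ids={"g05_b"})
        assert base - reduced == {"OG000002"}

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            select_core(toy_table(), 1.5)


class TestErosionShrinksCore:
    def test_core_size_monotone_in_deletion_rate(self):
        # same seed: a higher deletion probability deletes a superset of
        # genes (draws are coupled), so shared gene content — the >90%
        # single-copy core over all emitted genes — can only shrink
        from erosym.pipeline import _translate
        from erosym.synthetic_data import SimConfig, simulate_dataset

        sizes = []
        for dp in (0.0, 0.5, 1.0, 2.0):
            res = simulate_dataset(SimConfig(seed=77, deletion_prob=dp))
            proteomes = {
                g.genome_id: {
                    gene.gene_id: _translate(g.gene_sequence(gene))
                    for gene in g.genes
                }
                for g in res.genomes
            }
            table = cluster_orthogroups(proteomes)
            sizes.append(len(select_core(table, 0.90)))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        assert sizes[0] > sizes[-1]


class TestSharedMatrix:
    def test_universal_all_ones_and_row_sums(self):
        t = toy_table()
        df, order = shared_matrix(t)
        assert set(order) == set(t.members)
        assert (df["OG000002"] == 1).all()
        for gid in t.genome_ids:
            expected = sum(1 for og in t.members if gid in t.members[og])
            assert df.loc[gid].sum() == expected

    def test_block_structure_recovered(self, rng):
        # two genome groups with disjoint accessory orthogroups
        members = {}
        for j in range(10):
            members[f"OGA{j:03d}"] = {f"ga{i}": [f"ga{i}_x{j}"] for i in range(4)}
            members[f"OGB{j:03d}"] = {f"gb{i}": [f"gb{i}_x{j}"] for i in range(4)}
        genomes = [f"ga{i}" for i in range(4)] + [f"gb{i}" for i in range(4)]
        t = OrthogroupTable(members, n_genomes=8, genome_ids=genomes)
        df, order = shared_matrix(t)
        # after clustering, columns of the same block should be contiguous:
        labels = ["A" if og.startswith("OGA") else "B" in og or "B" for og in order]
        blocks = [og[2] for og in order]
        switches = sum(a != b for a, b in zip(blocks, blocks[1:]))
        assert switches == 1  # perfectly separated blocks
        # within-block density > between-block density
        a_rows, b_cols = df.loc[[f"ga{i}" for i in range(4)]], [c for c in df if c.startswith("OGA")]
        within = a_rows[b_cols].values.mean()
        between = df.loc[[f"gb{i}" for i in range(4)], b_cols].values.mean()
        assert within > between
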