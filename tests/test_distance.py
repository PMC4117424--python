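"""Distance computations, checked against the exhaustive lattice oracle."""

import random

import numpy as np
import pytest

from cnvphylo.core import Bounds, ChromosomeMap, EventKind, l1_distance
from cnvphylo.distance import (
    DistanceContext,
    LandingTable,
    Model,
    bfs_distance_oracle,
    boundary_sensitive_sequence,
    chromosome_sd_cd_distance,
    model_distance,
    sd_cd_distance,
    sd_cd_gd_distance,
    witness_sequence,
)

from conftest import random_config, random_layout


class TestChromosomeSdCd:
    @pytest.mark.parametrize(
        "x,y,cost,t",
        [
            ((2, 2), (3, 3), 1, 1),  # one chromosome gain
            ((3, 3, 3, 9), (1, 1, 1, 8), 3, -2),  # two losses + one SD gain
            ((2, 5), (4, 1), 6, 0),  # SD only
            ((7,), (2,), 5, 0),  # singleton chromosome: CD == SD
        ],
    )
    def test_frozen_examples(self, x, y, cost, t):
        res = chromosome_sd_cd_distance(x, y)
        assert (res.cost, res.cd_shift) == (cost, t)

    def test_cost_identity(self):
        res = chromosome_sd_cd_distance((4, 1, 3), (2, 2, 2))
        assert res.cost == abs(res.cd_shift) + sum(abs(v) for v in res.sd_moves)

    def test_even_pair_has_even_shift(self):
        """On a multi-probe chromosome, an optimal path between even
        sub-configurations uses an even number of CD events (an odd count
        forces one extra SD per gene, never minimal)."""
        rng = random.Random(5)
        for _ in range(200):
            k = rng.randint(2, 4)
            x = tuple(2 * rng.randint(0, 4) for _ in range(k))
            y = tuple(2 * rng.randint(0, 4) for _ in range(k))
            assert chromosome_sd_cd_distance(x, y).cd_shift % 2 == 0


class TestSdCdDistance:
    def test_identity_and_decomposition(self, six_probe_map):
        a = (2, 3, 1, 0, 4, 2)
        assert sd_cd_distance(a, a, six_probe_map) == 0

    def test_frozen_example(self):
        m = ChromosomeMap(["a", "b", "c", "d"], ["chr1", "chr1", "chr2", "chr3"])
        assert sd_cd_distance((2, 2, 2, 2), (3, 3, 1, 2), m) == 2

    def test_singleton_chromosomes_reduce_to_l1(self):
        rng = random.Random(1)
        m = ChromosomeMap.singletons(4)
        for _ in range(50):
            a = random_config(rng, 4, 9)
            b = random_config(rng, 4, 9)
            assert sd_cd_distance(a, b, m) == l1_distance(a, b)

    def test_symmetry(self):
        rng = random.Random(2)
        for _ in range(50):
            m = random_layout(rng, 4)
            a = random_config(rng, 4, 9)
            b = random_config(rng, 4, 9)
            assert sd_cd_distance(a, b, m) == sd_cd_distance(b, a, m)

    def test_length_mismatch(self, pair_map):
        with pytest.raises(ValueError):
            sd_cd_distance((1, 2, 3), (1, 2, 3), pair_map)


class TestBoundarySensitiveSequence:
    def test_empty_for_identical(self, pair_map):
        assert len(boundary_sensitive_sequence((2, 2), (2, 2), pair_map)) == 0

    def test_single_cd_gain(self, pair_map):
        seq = boundary_sensitive_sequence((2, 2), (3, 3), pair_map)
        assert [e.kind for e in seq.events] == [EventKind.CD_GAIN]

    def test_interleaving_at_upper_bound(self):
        """(3,3,3,9) -> (1,1,1,8): the SD gain of the last probe must wait
        for a CD loss, or the intermediate would hit 10."""
        m = ChromosomeMap(["a", "b", "c", "d"], ["chr1"] * 4)
        seq = boundary_sensitive_sequence((3, 3, 3, 9), (1, 1, 1, 8), m)
        assert len(seq) == 3
        seq.replay(m)  # raises if any intermediate leaves [0, 9]
        kinds = [e.kind for e in seq.events]
        gain_pos = kinds.index(EventKind.SD_GAIN)
        assert EventKind.CD_LOSS in kinds[:gain_pos]

    def test_random_pairs_replay_to_distance(self):
        rng = random.Random(3)
        for _ in range(150):
            G = rng.randint(1, 5)
            m = random_layout(rng, G)
            a = random_config(rng, G, 9)
            b = random_config(rng, G, 9)
            seq = boundary_sensitive_sequence(a, b, m)
            assert len(seq) == sd_cd_distance(a, b, m)
            seq.replay(m)


class TestSdCdGdDistance:
    @pytest.mark.parametrize(
        "a,b,layout,expected",
        [
            ((2, 2, 2, 2), (2, 2, 2, 2), "singletons", 0),
            ((2, 2), (4, 4), "singletons", 1),  # one GD
            ((2, 2), (5, 5), "shared", 2),  # GD then CD gain
            ((2, 2), (4, 6), "singletons", 2),  # SD gain then GD
            ((2, 2, 2, 2), (8, 8, 8, 8), "singletons", 2),  # GD, GD
        ],
    )
    def test_frozen_examples(self, a, b, layout, expected):
        G = len(a)
        m = (
            ChromosomeMap.singletons(G)
            if layout == "singletons"
            else ChromosomeMap([f"p{i}" for i in range(G)], ["chr1"] * G)
        )
        assert sd_cd_gd_distance(a, b, m) == expected

    def test_gd_saves_over_sd_cd(self, pair_map):
        assert sd_cd_distance((2, 2), (5, 5), pair_map) == 3
        assert sd_cd_gd_distance((2, 2), (5, 5), pair_map) == 2

    def test_asymmetry(self, pair_map):
        assert sd_cd_gd_distance((2, 2), (4, 4), pair_map) == 1
        assert sd_cd_gd_distance((4, 4), (2, 2), pair_map) == 2

    def test_even_target_single_doubling_decomposition(self):
        """For even targets b reachable with one GD, the cost decomposes as
        SD/CD edits to b/2 plus the doubling."""
        rng = random.Random(7)
        for _ in range(100):
            G = rng.randint(1, 4)
            m = random_layout(rng, G)
            a = random_config(rng, G, 4)
            b = tuple(2 * v for v in random_config(rng, G, 4))
            via_gd = 1 + sd_cd_distance(a, tuple(v // 2 for v in b), m)
            d = sd_cd_gd_distance(a, b, m)
            assert d <= via_gd
            if via_gd <= sd_cd_distance(a, b, m):
                assert d == via_gd or d < via_gd

    def test_model_monotonicity(self):
        """Richer event repertoires never increase the distance."""
        rng = random.Random(11)
        for _ in range(100):
            G = rng.randint(1, 4)
            m = random_layout(rng, G)
            a = random_config(rng, G, 9)
            b = random_config(rng, G, 9)
            d_l1 = model_distance(a, b, Model.SD, m)
            d_sdcd = model_distance(a, b, Model.SD_CD, m)
            d_sdgd = model_distance(a, b, Model.SD_GD, m)
            d_full = model_distance(a, b, Model.SD_CD_GD, m)
            assert d_full <= min(d_sdcd, d_sdgd) <= max(d_sdcd, d_sdgd) <= d_l1

    def test_model_dispatch(self, pair_map):
        m = ChromosomeMap.singletons(2)
        assert model_distance((1, 2), (2, 2), Model.SD, m) == 1
        assert model_distance((2, 2), (4, 4), Model.SD_GD, m) == 1
        with pytest.raises(ValueError):
            model_distance((1, 2), (2, 2), "bogus", m)

    def test_sd_cd_on_singletons_equals_sd(self):
        rng = random.Random(13)
        m = ChromosomeMap.singletons(3)
        for _ in range(50):
            a = random_config(rng, 3, 9)
            b = random_config(rng, 3, 9)
            assert model_distance(a, b, Model.SD_CD, m) == model_distance(
                a, b, Model.SD, m
            )


class TestOracleAgreement:
    def test_all_models_match_bfs(self):
        rng = random.Random(17)
        for _ in range(120):
            G = rng.randint(1, 4)
            ub = rng.randint(2, 6)
            bd = Bounds(0, ub)
            m = random_layout(rng, G)
            a = random_config(rng, G, ub)
            b = random_config(rng, G, ub)
            for model in Model:
                got = DistanceContext(model, m, bd).distance(a, b)
                assert got == bfs_distance_oracle(a, b, model, m, bd)

    def test_oracle_guard(self):
        m = ChromosomeMap.singletons(12)
        with pytest.raises(ValueError, match="too large"):
            bfs_distance_oracle((2,) * 12, (3,) * 12, Model.SD, m, Bounds(0, 9))


class TestWitnessSequences:
    def test_replay_length_and_purity(self):
        """Witnesses replay in bounds, match the distance, and never mix
        gains with losses of one probe or one chromosome."""
        rng = random.Random(19)
        for _ in range(150):
            G = rng.randint(1, 4)
            m = random_layout(rng, G)
            bd = Bounds(0, 9)
            a = random_config(rng, G, 9)
            b = random_config(rng, G, 9)
            for model in (Model.SD_CD, Model.SD_CD_GD):
                ctx = DistanceContext(model, m, bd)
                seq = witness_sequence(a, b, ctx)
                assert len(seq) == ctx.distance(a, b)
                seq.replay(m, bd)
                # Between GD events the SD/CD segments must be sign-pure.
                segment: list = []
                for ev in seq.events + [None]:
                    if ev is None or ev.kind is EventKind.GD:
                        sd_dirs: dict = {}
                        cd_dirs: dict = {}
                        for e in segment:
                            d = 1 if e.kind in (EventKind.SD_GAIN, EventKind.CD_GAIN) else -1
                            book = sd_dirs if e.kind.value.startswith("sd") else cd_dirs
                            assert book.setdefault(e.target, d) == d
                        segment = []
                    else:
                        segment.append(ev)


class TestLandingTable:
    def test_batch_matches_scalar(self):
        rng = random.Random(23)
        m = random_layout(rng, 4)
        ctx = DistanceContext(Model.SD_CD_GD, m, Bounds(0, 9))
        targets = [random_config(rng, 4, 9) for _ in range(6)]
        sources = np.asarray([random_config(rng, 4, 9) for _ in range(8)])
        table = LandingTable(ctx, targets)
        got = table.dist_from(sources)
        for i, src in enumerate(sources):
            for j, tgt in enumerate(targets):
                assert got[i, j] == ctx.distance(tuple(src), tgt)
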