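import numpy as np
import pytest

from tomospat.geometry import euler_to_matrix, random_eulers
from tomospat.particles import ParticleRecord
from tomospat.ribosome import (
    FrameConfig,
    RibosomeContextModel,
    classify_side,
    ets_enrichment,
    pair_to_nearest_ribosome,
    to_ribosome_frame,
)

from conftest import make_set


def ribosome_at(pos, euler=(0.0, 0.0, 0.0)):
    return ParticleRecord("r0", "t", np.asarray(pos, float), euler, "ribosome")


class TestPairing:
    def test_picks_nearer_ribosome(self):
        trics = make_set([[0, 0, 0]], states=["open"])
        ribos = make_set([[30, 0, 0], [60, 0, 0]], states=["ribosome"] * 2)
        pairs = pair_to_nearest_ribosome(trics, ribos, max_dist=100)
        assert pairs.loc[0, "ribosome_id"] == "p0000"
        assert pairs.loc[0, "distance"] == 30.0

    def test_beyond_max_dist_unpaired(self):
        trics = make_set([[0, 0, 0]], states=["open"])
        ribos = make_set([[120, 0, 0]], states=["ribosome"])
        pairs = pair_to_nearest_ribosome(trics, ribos, max_dist=100)
        assert pairs["ribosome_id"].isna().all()

    def test_tomogram_without_ribosomes_reports_unpaired(self):
        trics = make_set([[0, 0, 0], [5, 5, 5]], states=["open"] * 2, tomogram=["a", "b"])
        ribos = make_set([[10, 0, 0]], states=["ribosome"], tomogram="a")
        pairs = pair_to_nearest_ribosome(trics, ribos, max_dist=100)
        assert pairs.set_index("tomogram_id")["ribosome_id"].isna()["b"]

    def test_matches_exhaustive_scan(self, rng):
        tpos = rng.uniform(0, 400, (200, 3))
        rpos = rng.uniform(0, 400, (150, 3))
        trics = make_set(tpos, states=["open"] * 200)
        ribos = make_set(rpos, states=["ribosome"] * 150)
        pairs = pair_to_nearest_ribosome(trics, ribos, max_dist=100)
        d = np.linalg.norm(tpos[:, None] - rpos[None], axis=2)
        for i in range(200):
            j = int(np.argmin(d[i]))
            if d[i, j] <= 100:
                assert pairs.loc[i, "ribosome_id"] == f"p{j:04d}"
            else:
                assert pairs.loc[i, "ribosome_id"] is None or np.isnan(
                    pairs.loc[i, "distance"]
                )


class TestFrameTransform:
    def test_tric_at_tunnel_maps_to_origin(self):
        cfg = FrameConfig((0, 0, -25), 100)
        ribo = ribosome_at([10, 20, 30], (40.0, 60.0, -20.0))
        tunnel = ribo.position + euler_to_matrix(ribo.orientation) @ cfg.offset
        np.testing.assert_allclose(to_ribosome_frame(tunnel, ribo, cfg), 0, atol=1e-9)

    def test_zero_rotation_offset_arithmetic(self):
        cfg = FrameConfig((0, 0, 10), 100)
        ribo = ribosome_at([0, 0, 0])
        np.testing.assert_allclose(
            to_ribosome_frame([0, 0, 0], ribo, cfg), [0, 0, -10], atol=1e-12
        )

    def test_forward_then_back_round_trip(self, rng):
        cfg = FrameConfig((3, -4, -24), 100)
        for e in random_eulers(50, rng):
            ribo = ribosome_at(rng.uniform(0, 500, 3), tuple(e))
            frame_true = rng.uniform(-40, 40, 3)
            R = euler_to_matrix(ribo.orientation)
            world = ribo.position + R @ (cfg.offset + frame_true)
            np.testing.assert_allclose(
                to_ribosome_frame(world, ribo, cfg), frame_true, atol=1e-9
            )

    def test_isometry(self, rng):
        cfg = FrameConfig((0, 0, -25), 100)
        ribo = ribosome_at([100, 50, 20], (12.0, 98.0, -140.0))
        pts = rng.uniform(0, 200, (30, 3))
        frames = np.array([to_ribosome_frame(p, ribo, cfg) for p in pts])
        d_before = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        d_after = np.linalg.norm(frames[:, None] - frames[None], axis=2)
        np.testing.assert_allclose(d_before, d_after, atol=1e-9)


class TestClassifySide:
    cfg = FrameConfig((0, 0, -25), 100)

    def test_along_tunnel_direction_is_ets(self):
        # tunnel direction is -z; a point below the centre is on the ETS
        assert classify_side([0, 0, -40], self.cfg) == "ETS"

    def test_boundary_plane_is_non_ets(self):
        # position relative to the centre (frame + offset) has zero component
        # along the centre-to-tunnel axis -> boundary -> non-ETS
        assert classify_side([5.0, 3.0, 25.0], self.cfg) == "non-ETS"

    def test_opposite_side_is_non_ets(self):
        assert classify_side([0, 0, 40], self.cfg) == "non-ETS"

    def test_isotropic_positions_split_evenly(self, rng):
        n = 4000
        directions = rng.standard_normal((n, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        rel = directions * rng.uniform(20, 60, (n, 1))  # isotropic about the centre
        frame_positions = rel - self.cfg.offset  # centre sits at -offset in the frame
        sides = [classify_side(p, self.cfg) for p in frame_positions]
        frac = np.mean([s == "ETS" for s in sides])
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(n)


class TestEnrichment:
    def test_all_on_ets_side(self):
        # zero-rotation ribosomes at origin of each tomogram; particles at -z
        trics = make_set([[50, 50, 20]], states=["open"])
        ribos = make_set([[50, 50, 60]], states=["ribosome"])
        res = ets_enrichment(trics, ribos, FrameConfig((0, 0, -25), 100), n_boot=50, seed=0)
        assert res.ets_fraction == 1.0

    def test_zero_pairs_raises(self):
        trics = make_set([[0, 0, 0]], states=["open"])
        ribos = make_set([[500, 500, 500]], states=["ribosome"])
        with pytest.raises(ValueError, match="no particle paired"):
            ets_enrichment(trics, ribos, FrameConfig((0, 0, -25), 100))

    def test_model_summary_and_per_state(self, rng):
        n = 200
        pos = rng.uniform(0, 1000, (n, 3))
        trics = make_set(pos, states=rng.choice(["open", "closed"], n).tolist())
        ribos = make_set(
            rng.uniform(0, 1000, (n, 3)),
            states=["ribosome"] * n,
            eulers=random_eulers(n, rng),
        )
        res = RibosomeContextModel(trics, ribos).fit(n_boot=100, seed=3)
        assert {"open", "closed", "all"} <= set(res.fractions["state"])
        lo, hi = res.ci_for("all")
        assert 0 <= lo <= res.ets_fraction <= hi <= 1
        assert "exit-tunnel-side" in res.summary()
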