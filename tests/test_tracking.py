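import numpy as np

from conftest import make_detection
from leukotrace.tracking import GateRule, TrackFragment, link, split_on_state
from leukotrace.synthetic import SimConfig, simulate


def moving_cell(frames, x0, y0, vx=0.0, vy=0.0, det_id=0, **kw):
    """Detections for one cell at constant velocity over given frames."""
    return {t: make_detection(frame=t, det_id=det_id, x=x0 + vx * i, y=y0 + vy * i, **kw)
            for i, t in enumerate(frames)}


def merge_dicts(*cell_dicts):
    out = {}
    for cd in cell_dicts:
        for t, d in cd.items():
            out.setdefault(t, []).append(d)
    return out


class TestGateRule:
    def test_growing_gate_reading(self):
        gate = GateRule()
        assert [gate.allowed_radius(g) for g in range(1, 6)] == [11, 22, 33, 44, 55]
        assert gate.allowed_radius(6) == 0.0

    def test_fixed_radius_alternative(self):
        gate = GateRule(fixed_radius=True)
        assert all(gate.allowed_radius(g) == 55 for g in range(1, 6))


class TestLinking:
    def test_two_separated_cells_give_two_full_fragments(self):
        a = moving_cell(range(10), 50, 50, vx=3, det_id=0)
        b = moving_cell(range(10), 300, 300, vy=3, det_id=1)
        frags = link(merge_dicts(a, b))
        assert len(frags) == 2
        assert all(fr.n_points == 10 for fr in frags)
        assert all(fr.start_reason == "appeared" and fr.end_reason == "video_end" for fr in frags)

    def test_gap_within_growing_gate_resumes_fragment(self):
        # last seen frame 4, reappears frame 7 (3-frame gap) 20 px away: 20 <= 33
        a = moving_cell(range(5), 100, 100, det_id=0)
        back = moving_cell(range(7, 12), 120, 100, det_id=0)
        frags = link(merge_dicts(a, back))
        assert len(frags) == 1
        assert frags[0].n_points == 10

    def test_jump_beyond_55px_at_max_gap_splits(self):
        a = moving_cell(range(5), 100, 100, det_id=0)
        far = moving_cell(range(9, 14), 160, 100, det_id=0)  # gap 5, 60 px > 55
        frags = link(merge_dicts(a, far))
        assert len(frags) == 2
        assert frags[0].end_reason == "gap_exceeded"

    def test_no_centroid_reused_across_fragments(self):
        rng = np.random.default_rng(1)
        cells = [moving_cell(range(20), 60 + 90 * i, 60 + 70 * j,
                             vx=rng.uniform(-2, 2), vy=rng.uniform(-2, 2), det_id=3 * j + i)
                 for i in range(3) for j in range(3)]
        frags = link(merge_dicts(*cells))
        seen = set()
        for fr in frags:
            for t, d in zip(fr.frames, fr.det_ids):
                assert (t, d) not in seen
                seen.add((t, d))

    def test_linking_invariant_to_global_translation(self):
        a = moving_cell(range(8), 50, 50, vx=4, det_id=0)
        b = moving_cell(range(8), 200, 100, vy=4, det_id=1)
        base = link(merge_dicts(a, b))
        a2 = moving_cell(range(8), 150, 30, vx=4, det_id=0)
        b2 = moving_cell(range(8), 300, 80, vy=4, det_id=1)
        moved = link(merge_dicts(a2, b2))
        assert [fr.det_ids for fr in base] == [fr.det_ids for fr in moved]
        assert [fr.frames for fr in base] == [fr.frames for fr in moved]


class TestMergeSplit:
    def scripted_merge_scenario(self):
        """Two cells converge, form a 3-cell-sized cluster for 10 frames,
        then separate again."""
        dets = {}
        for t in range(10):  # approach
            dets[t] = [
                make_detection(frame=t, det_id=0, x=100 + 5 * t, y=100, area=800,
                               single_multi="single", est_count=1),
                make_detection(frame=t, det_id=1, x=200 - 5 * t, y=100, area=800,
                               single_multi="single", est_count=1),
            ]
        for t in range(10, 20):  # one big cluster detection
            dets[t] = [make_detection(frame=t, det_id=0, x=150, y=100, area=2400,
                                      single_multi="multiple", est_count=3)]
        for t in range(20, 30):  # separation
            off = 5 * (t - 19)
            dets[t] = [
                make_detection(frame=t, det_id=0, x=150 - off, y=100, area=800,
                               single_multi="single", est_count=1),
                make_detection(frame=t, det_id=1, x=150 + off, y=100, area=800,
                               single_multi="single", est_count=1),
            ]
        return dets

    def test_merge_then_split_fragment_accounting(self):
        frags = link(self.scripted_merge_scenario())
        assert len(frags) == 5
        pre = [f for f in frags if f.end_reason == "merged"]
        cluster = [f for f in frags if f.is_cluster]
        post = [f for f in frags if f.start_reason == "split_from_merge"]
        assert len(pre) == 2 and len(cluster) == 1 and len(post) == 2
        assert cluster[0].start_reason == "merged"
        assert cluster[0].end_reason == "split_from_merge"
        assert all(f.parent_fragment == cluster[0].fragment_id for f in post)

    def test_single_cell_is_unaffected_by_merge_logic(self):
        a = moving_cell(range(15), 80, 80, vx=2, det_id=0, single_multi="single")
        assert len(link(merge_dicts(a))) == 1

    def test_overlap_event_common_centroid_and_restart(self):
        # luminal cell crawls over an abluminal one: common centroid during
        # the overlap, fresh fragments after it ends
        lum = moving_cell(range(8), 100, 100, vx=6, det_id=0,
                          single_multi="single", fracs=(1.0, 0.0, 0.0))
        ab = moving_cell(range(8), 148, 100, det_id=1,
                         single_multi="single", fracs=(0.0, 0.0, 1.0))
        dets = merge_dicts(lum, ab)
        for t in range(8, 13):
            dets[t] = [make_detection(frame=t, det_id=0, x=148, y=100, area=2500,
                                      single_multi="multiple", est_count=3,
                                      fracs=(0.5, 0.0, 0.5))]
        for t in range(13, 20):
            off = 6 * (t - 12)
            dets[t] = [
                make_detection(frame=t, det_id=0, x=148 + off, y=100,
                               single_multi="single", fracs=(1.0, 0.0, 0.0)),
                make_detection(frame=t, det_id=1, x=148, y=100,
                               single_multi="single", fracs=(0.0, 0.0, 1.0)),
            ]
        frags = link(dets)
        clusters = [f for f in frags if f.is_cluster]
        assert len(clusters) == 1
        assert len([f for f in frags if f.start_reason == "split_from_merge"]) == 2


class TestSplitOnState:
    def test_state_change_splits_into_chained_subfragments(self):
        fr = TrackFragment(fragment_id=0)
        for t in range(110):
            fr.append(t, float(t), 0.0, "luminal" if t < 50 else "abluminal", t)
        subs = split_on_state([fr])
        assert [s.n_points for s in subs] == [50, 60]
        assert subs[1].parent_fragment == subs[0].fragment_id
        assert subs[0].end_reason == "state_change"
        assert subs[1].start_reason == "state_change"
        # concatenation reconstructs the parent sequence exactly
        frames = [t for s in subs for t in s.frames]
        assert frames == list(range(110))

    def test_constant_state_fragment_unchanged(self):
        fr = TrackFragment(fragment_id=3)
        for t in range(5):
            fr.append(t, 0.0, 0.0, "luminal", t)
        assert split_on_state([fr]) == [fr]

    def test_flicker_yields_three_subfragments_without_smoothing(self):
        fr = TrackFragment(fragment_id=0)
        for t, s in enumerate(["luminal", "abluminal", "luminal"]):
            fr.append(t, 0.0, 0.0, s, t)
        assert len(split_on_state([fr])) == 3


def test_point_assignment_accuracy_on_simulated_truth():
    """Well-separated simulated cells: >=95% of linked points belong to the
    fragment's majority ground-truth cell."""
    cfg = SimConfig(n_frames=60, size=512, n_cells=10, clustering_rate=0.0,
                    fraction_transmigrating=0.0, immobile_fraction=0.2, seed=31)
    _, truth = simulate(cfg)
    dets = {}
    for t, grp in truth.cells.groupby("frame"):
        dets[t] = [make_detection(frame=t, det_id=i, x=row.x, y=row.y,
                                  single_multi="single")
                   for i, row in enumerate(grp.itertuples())]
    # remember which true cell produced each det_id
    det_to_cell = {}
    for t, grp in truth.cells.groupby("frame"):
        for i, row in enumerate(grp.itertuples()):
            det_to_cell[(t, i)] = row.cell_id
    frags = link(dets)
    correct = total = 0
    for fr in frags:
        owners = [det_to_cell[(t, d)] for t, d in zip(fr.frames, fr.det_ids)]
        majority = max(set(owners), key=owners.count)
        correct += sum(o == majority for o in owners)
        total += len(owners)
    assert total >= 0.95 * 10 * 60  # nearly all detections were linked
    assert correct / total >= 0.95
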