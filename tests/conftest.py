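import numpy as np
import pytest

from densetrack.malc import Detection
from densetrack.motion import HypothesisScore, KinematicState, MotionScoreState
from densetrack.hypotheses import TrackHypothesis


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_detection(frame, x, y, det_id=1):
    return Detection(frame_index=frame, centroid=(y, x), detection_id=det_id)


def make_hypothesis(det_ids, tree_id=0, leaf_id=0, s_ltm=0.0, ic=None, s_aa=0.0,
                    birth_frame=0):
    """Fabricate a leaf hypothesis from a per-frame detection-id sequence
    (None means a dummy at that frame)."""
    dets = []
    for i, d in enumerate(det_ids):
        frame = birth_frame + i
        if d is None:
            dets.append(Detection.dummy(frame))
        else:
            dets.append(Detection(frame_index=frame, centroid=(0.0, 0.0), detection_id=d))
    n_real = sum(1 for d in dets if not d.is_dummy)
    hyp = TrackHypothesis(
        detections=dets,
        birth_frame=birth_frame,
        kin=KinematicState(x=np.zeros(4), p=np.eye(4)),
        motion=MotionScoreState(s_aa=s_aa, ic=n_real if ic is None else ic),
        score=HypothesisScore(s_ltm=s_ltm, s_stm=0.0),
        tree_id=tree_id,
        leaf_id=leaf_id,
    )
    hyp.peak_score = s_ltm
    return hyp
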