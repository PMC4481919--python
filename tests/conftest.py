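import numpy as np
import pytest

from gazelab.gaze_io import EyeSample, GazeSample, RawGazeRecord, SessionMeta
from gazelab.ivt_filter import ScreenGeometry

# the recorded dialect as the logger wrote it, including the stray
# whitespace inside attribute values that the parser must tolerate
RAW_GAZE_XML = """\
<user date="2014-05-22" id=" 12" sessionid="899" time="09:20:15">
 <exercise id="puzzle" level="Level5" mode="performance">
  <eyedata>
   <timestamp time=" 1167610729217997 ">
    <left_eye pupil_diam="3.0435333252" validity="0" x=" 134.831732304" y=" 64.8299084174"/>
    <right_eye pupil_diam="2.89215087891" validity="0" x=" 69.9537996816" y=" 59.426052033"/>
   </timestamp>
  </eyedata>
 </exercise>
</user>
"""

FIXATION_XML = """\
<user date="2014-05-22" id="12" sessionid="897" time="09:15:27">
 <exercise id="puzzle" level="Level1" mode="performance">
  <fixationData>
   <fixation>
    <time duration=" 212.356933594 " end_time=" 1.1676104137 e+12" start_time=" 1.16761041349 e+12">
     <position x=" 54.2251062717 " y=" 130.508713537 "/>
    </time>
   </fixation>
  </fixationData>
 </exercise>
</user>
"""


@pytest.fixture
def geometry() -> ScreenGeometry:
    return ScreenGeometry()


@pytest.fixture
def raw_gaze_xml() -> str:
    return RAW_GAZE_XML


@pytest.fixture
def fixation_xml() -> str:
    return FIXATION_XML


def make_samples(positions, dt_ms=1000.0 / 30.0, t0_ms=0.0, valid=None):
    """Binocular samples at a fixed rate; both eyes at the given point.

    ``positions`` is a sequence of (x, y) in screen mm; ``valid`` an
    optional boolean mask (False -> both eyes invalid).
    """
    samples = []
    for k, (x, y) in enumerate(positions):
        ok = True if valid is None else bool(valid[k])
        eye = (
            EyeSample(x=float(x), y=float(y), pupil_diam=3.0, validity=0)
            if ok
            else EyeSample(x=-1.0, y=-1.0, pupil_diam=-1.0, validity=4)
        )
        samples.append(
            GazeSample(timestamp_us=(t0_ms + k * dt_ms) * 1000.0, left=eye, right=eye)
        )
    return samples


def make_record(positions, dt_ms=1000.0 / 30.0, valid=None, level="Level1"):
    return RawGazeRecord(
        meta=SessionMeta(user_id="t", level=level),
        samples=make_samples(positions, dt_ms=dt_ms, valid=valid),
    )


def hold_positions(point, n):
    return [point] * n
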