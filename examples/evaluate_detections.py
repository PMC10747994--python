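"""COCO-style AP/AR on a small hand-built detection scenario.

Three images, four ground-truth boxes, detections of varying quality;
prints AP at every IoU threshold plus the AP/AP50/AP75/AR summary.
"""

import numpy as np

from abfp import BoxSet, evaluate
from abfp.evaluation import IOU_THRESHOLDS

gts = [
    BoxSet(boxes=[[10, 10, 30, 30], [50, 50, 70, 80]], image_id=0),
    BoxSet(boxes=[[20, 20, 44, 40]], image_id=1),
    BoxSet(boxes=[[5, 5, 25, 25]], image_id=2),
]
dets = [
    # image 0: one perfect hit, one slightly shifted hit
    BoxSet(boxes=[[10, 10, 30, 30], [53, 52, 73, 82]], scores=[0.95, 0.80], image_id=0),
    # image 1: a loose hit and a false positive
    BoxSet(boxes=[[24, 22, 48, 44], [70, 70, 90, 90]], scores=[0.70, 0.60], image_id=1),
    # image 2: missed entirely
    BoxSet(boxes=np.zeros((0, 4)), scores=np.zeros(0), image_id=2),
]

result = evaluate(dets, gts)
for t, ap in zip(IOU_THRESHOLDS, result.per_threshold_AP):
    print(f"AP@{t:.2f} = {ap:.3f}")
print(f"\nAP   = {result.AP:.3f}  (mean over the ten thresholds)")
print(f"AP50 = {result.AP50:.3f}  (loose localisation)")
print(f"AP75 = {result.AP75:.3f}  (strict localisation)")
print(f"AR   = {result.AR:.3f}  (mean recall over the same thresholds)")
# AP falls as the IoU threshold tightens: the shifted and loose boxes stop
# counting as matches, which is exactly what AP75 < AP50 expresses.
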