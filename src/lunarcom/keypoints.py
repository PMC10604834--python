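"""BODY_25 keypoint layout.

The markerless pose producer emits 25 keypoints per person and frame
(x, y, confidence).  Index constants below follow the BODY_25 ordering;
the segment table in :mod:`lunarcom.anthropometry` refers to joints by
these indices, never by hard-coded numbers in logic.
"""

N_KEYPOINTS = 25

NOSE = 0
NECK = 1            # mid-shoulder point
R_SHOULDER = 2
R_ELBOW = 3
R_WRIST = 4
L_SHOULDER = 5
L_ELBOW = 6
L_WRIST = 7
MID_HIP = 8         # pelvis reference point
R_HIP = 9
R_KNEE = 10
R_ANKLE = 11
L_HIP = 12
L_KNEE = 13
L_ANKLE = 14
R_EYE = 15
L_EYE = 16
R_EAR = 17
L_EAR = 18
L_BIG_TOE = 19
L_SMALL_TOE = 20
L_HEEL = 21
R_BIG_TOE = 22
R_SMALL_TOE = 23
R_HEEL = 24

#: pelvis keypoint used as the reference point for CoM displacement
PELVIS = MID_HIP

NAMES = (
    "Nose", "Neck", "RShoulder", "RElbow", "RWrist",
    "LShoulder", "LElbow", "LWrist", "MidHip", "RHip",
    "RKnee", "RAnkle", "LHip", "LKnee", "LAnkle",
    "REye", "LEye", "REar", "LEar", "LBigToe",
    "LSmallToe", "LHeel", "RBigToe", "RSmallToe", "RHeel",
)
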