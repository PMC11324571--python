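"""Dataset-split bookkeeping: combine published source-dataset counts
into the unified training split, and carve frame-level test splits out
of simulated full-procedure videos."""

from cadeval import DatasetCounts, SimConfig, build_ucd, rc_ssp, simulate_dataset
from cadeval.splits import split_frame_masks, summarize_split

ucd = build_ucd(
    DatasetCounts("KUMC", 37_899, 35_981, 1_918, 80),
    DatasetCounts("SUN", 158_690, 49_136, 109_554, 100),
    DatasetCounts("LDPolypVideo", 139_640, 33_875, 105_765, 200),
)
print("unified training split:", ucd.summary)

videos, tracks = simulate_dataset(SimConfig(n_videos=2, fps=5.0, video_len_s=120.0, seed=7))
vmap = {v.video_id: v for v in videos}
ssp = rc_ssp(videos, tracks)
print("full videos:        ", summarize_split(
    type(ssp)(name="ALL", members=[type(m)(m.member_id) for m in ssp.members]), vmap
))
print("start-stop-polyp:   ", ssp.summary)
# The restriction keeps every positive frame but drops the negatives
# outside polyp intervals - the frames where FP events mostly live.
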