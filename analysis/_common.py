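"""Shared study conditions for the analysis scripts.

One place defines the MEA recording designs, the synthetic TF motif
panel and the qPCR plate layout, so every script (and the acceptance
rerun) analyses the same conditions.
"""

import numpy as np
import pandas as pd

from lncfunnel.io_formats import PFMRecord

# 24-well plate geometry of the recording system: 16 electrodes/well,
# 15-minute recordings
N_ELECTRODES = 16
DURATION_S = 900.0

# control-like wells: active background, planted single-electrode bursts
# and synchronized network bursts
CONTROL_RASTER_SPEC = dict(
    n_electrodes=N_ELECTRODES,
    duration=DURATION_S,
    base_rate=1.0,
    burst_spec=(10, 8, 0.02),
    network_spec=(12, 8, 80),
    sync_level=0.3,
)

# knockdown-like wells: sparse, desynchronized activity
KD_RASTER_SPEC = dict(
    n_electrodes=N_ELECTRODES,
    duration=DURATION_S,
    base_rate=0.25,
    burst_spec=(2, 6, 0.03),
    network_spec=(2, 6, 55),
    sync_level=0.05,
)


def _consensus_pfm(motif_id: str, tf_name: str, consensus: str) -> PFMRecord:
    counts = np.zeros((4, len(consensus)))
    for i, base in enumerate(consensus):
        counts["ACGT".index(base), i] = 20.0
    return PFMRecord(motif_id, tf_name, counts)


#: synthetic stand-ins for a glial TF motif panel (11-mers: at a scan
#: p-value of 1e-4 the exact threshold admits at most one mismatch)
SHARP_PFM = _consensus_pfm("SYN0001", "TF_A", "ACGTACGTACG")
TF_PANEL = [
    _consensus_pfm("SYN0001", "TF_A", "ACGTACGTACG"),
    _consensus_pfm("SYN0002", "TF_B", "GGATTACCAGT"),
    _consensus_pfm("SYN0003", "TF_C", "TTCGCAAGCGA"),
    _consensus_pfm("SYN0004", "TF_D", "CATGCCAATGG"),
]


def fixed_qpcr_table() -> pd.DataFrame:
    """A small knockdown-experiment Ct table (target vs reference gene)
    with a clear ~4-fold suppression in the treated samples."""
    rows = [
        ("ctl_1", "control", 24.1, 18.0),
        ("ctl_2", "control", 23.9, 17.9),
        ("ctl_3", "control", 24.0, 18.1),
        ("kd_1", "gapmer", 26.2, 18.0),
        ("kd_2", "gapmer", 26.0, 17.8),
        ("kd_3", "gapmer", 26.1, 18.2),
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "condition", "ct_target", "ct_reference"]
    )
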