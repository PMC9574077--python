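"""Published reference values for provincial health-system efficiency.

These are the published 2009-2020 provincial averages of overall,
resource-allocation (stage 1) and service-operation (stage 2) efficiency
for mainland China's 31 provincial units, together with the published
direct/indirect/total spillover-effect estimates of the log covariates.
They serve as *inputs* to internal-arithmetic consistency checks (column
means, the product identity, effects additivity); the package never fits to
them.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "PROVINCIAL_AVERAGE_EFFICIENCY",
    "PUBLISHED_EFFECTS",
    "provincial_average_table",
    "published_effects_table",
]

#: province -> (overall, stage-1 resource allocation, stage-2 service operation)
PROVINCIAL_AVERAGE_EFFICIENCY = {
    "Beijing": (0.3210, 0.5617, 0.5686),
    "Tianjin": (0.5076, 0.5672, 0.8930),
    "Hebei": (0.7510, 0.7815, 0.9585),
    "Shanxi": (0.5693, 0.8644, 0.6610),
    "Inner Mongolia": (0.4041, 0.6399, 0.6327),
    "Liaoning": (0.6924, 0.9590, 0.7175),
    "Jilin": (0.5808, 0.7216, 0.7942),
    "Heilongjiang": (0.6738, 0.8418, 0.7953),
    "Shanghai": (0.5255, 0.5255, 1.0000),
    "Jiangsu": (0.7844, 0.7844, 1.0000),
    "Zhejiang": (0.6756, 0.8204, 0.8230),
    "Anhui": (0.6218, 0.6234, 0.9977),
    "Fujian": (0.5919, 0.6755, 0.8758),
    "Jiangxi": (0.6196, 0.6196, 1.0000),
    "Shandong": (0.9546, 0.9803, 0.9738),
    "Henan": (0.7939, 0.7963, 0.9968),
    "Hubei": (0.6724, 0.7711, 0.8710),
    "Hunan": (0.7170, 0.8483, 0.8453),
    "Guangdong": (0.7168, 0.7168, 1.0000),
    "Guangxi": (0.6162, 0.6805, 0.9059),
    "Hainan": (0.4132, 0.5136, 0.8063),
    "Chongqing": (0.5482, 0.6448, 0.8503),
    "Sichuan": (0.6869, 0.7527, 0.9156),
    "Guizhou": (0.4957, 0.5894, 0.8449),
    "Yunnan": (0.5450, 0.5854, 0.9347),
    "Tibet": (0.1902, 0.2571, 0.7463),
    "Shaanxi": (0.5327, 0.7826, 0.6814),
    "Gansu": (0.5192, 0.6101, 0.8524),
    "Qinghai": (0.2638, 0.3972, 0.6643),
    "Ningxia": (0.4305, 0.5727, 0.7532),
    "Xinjiang": (0.4882, 0.7179, 0.6838),
}

#: covariate -> (direct, indirect, total) published effect estimates
PUBLISHED_EFFECTS = {
    "lnpgdp": (-0.7022, 1.1840, 0.4818),
    "lnfiscal": (-0.2856, -0.4215, -0.7072),
    "lnurban": (-0.1785, -0.2546, -0.4331),
    "lnedu": (-0.0289, -0.0923, -0.1212),
    "lndepend": (0.2505, 0.3039, 0.5544),
}


def provincial_average_table() -> pd.DataFrame:
    """The published provincial averages as a DataFrame (31 rows)."""
    return pd.DataFrame(
        [(p, *v) for p, v in PROVINCIAL_AVERAGE_EFFICIENCY.items()],
        columns=["unit", "overall", "stage1", "stage2"],
    )


def published_effects_table() -> pd.DataFrame:
    """The published direct/indirect/total effects as a DataFrame."""
    return pd.DataFrame(
        [(c, *v) for c, v in PUBLISHED_EFFECTS.items()],
        columns=["covariate", "direct", "indirect", "total"],
    )
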