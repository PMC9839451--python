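"""qPCR arithmetic: ddCt relative expression and hMeDIP recovery/enrichment.

The hMeDIP percent-recovery formula compares the immunoprecipitate Ct to
a 10% input aliquot; diluting the input tenfold costs log2(10) = 3.3219
cycles, conventionally written as the constant 3.32.  The literal 3.32 is
the default so published numbers reproduce bit-for-bit; a high-precision
mode substitutes log2(10).
"""
from __future__ import annotations

import math
from typing import Iterable

INPUT_DILUTION_CT = 3.32  # printed convention for log2(10)


def mean_ct(values: Iterable[float]) -> float:
    """Average technical replicates on the Ct (cycle) scale."""
    values = list(values)
    if not values:
        raise ValueError("no Ct values to average")
    return sum(values) / len(values)


def ddct_fold(
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
    ct_target_trt: float,
    ct_ref_trt: float,
) -> float:
    """Relative expression by the ddCt method.

    dCt = Ct(reference) - Ct(target) per condition; the fold change of
    the treated condition relative to control is 2**(dCt_trt - dCt_ctrl),
    so the control fold is 1 by construction.  Adding a constant to all
    four Cts (a plate offset) leaves the fold unchanged.
    """
    dct_ctrl = ct_ref_ctrl - ct_target_ctrl
    dct_trt = ct_ref_trt - ct_target_trt
    return 2.0 ** (dct_trt - dct_ctrl)


def hmedip_recovery(
    ct_input_10pct: float,
    ct_ip: float,
    high_precision: bool = False,
) -> float:
    """Percent recovery of an immunoprecipitated locus relative to input.

    ``2**((Ct(10% input) - 3.32) - Ct(IP)) * 100``.  Exactly 100% when
    the IP Ct sits 3.32 cycles below the 10%-input Ct.
    """
    const = math.log2(10) if high_precision else INPUT_DILUTION_CT
    return 2.0 ** ((ct_input_10pct - const) - ct_ip) * 100.0


def hmedip_enrichment(recovery_locus: float, recovery_igg: float) -> float:
    """Recovery at the specific locus over recovery with the IgG control."""
    if recovery_igg <= 0:
        raise ValueError("IgG recovery must be > 0 for a defined enrichment")
    return recovery_locus / recovery_igg
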