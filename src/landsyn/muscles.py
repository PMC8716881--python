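"""Canonical muscle set and joint flexor/extensor groupings.

The pipeline analyses 13 muscles of the landing leg, always in the fixed
order below. Abbreviations follow common surface-EMG usage:

====  =========================
ME    gluteus medius
MA    gluteus maximus
FL    tensor fasciae latae
RF    rectus femoris
VM    vastus medialis
VL    vastus lateralis
ST    semitendinosus
BF    biceps femoris (long head)
TA    tibialis anterior
PL    peroneus longus
GM    gastrocnemius medialis
GL    gastrocnemius lateralis
SO    soleus
====  =========================
"""

from __future__ import annotations

MUSCLES: tuple[str, ...] = (
    "ME", "MA", "FL", "RF", "VM", "VL", "ST",
    "BF", "TA", "PL", "GM", "GL", "SO",
)

N_MUSCLES: int = len(MUSCLES)

JOINTS: tuple[str, ...] = ("hip", "knee", "ankle")

# Sagittal-plane flexor/extensor groups per joint used by the coactivation
# index. For the ankle, "flexor" means dorsiflexor and "extensor" plantar
# flexor. RF is bi-articular and appears as both hip flexor and knee extensor.
FLEXORS: dict[str, tuple[str, ...]] = {
    "hip": ("FL", "RF"),
    "knee": ("ST", "BF"),
    "ankle": ("TA",),
}

EXTENSORS: dict[str, tuple[str, ...]] = {
    "hip": ("ME", "MA"),
    "knee": ("RF", "VM", "VL"),
    "ankle": ("PL", "GM", "GL", "SO"),
}


def muscle_indices(labels: tuple[str, ...], subset: tuple[str, ...]) -> list[int]:
    """Positions of ``subset`` muscles within an ordered label tuple."""
    missing = [m for m in subset if m not in labels]
    if missing:
        raise KeyError(f"muscles {missing} not present in labels {labels}")
    return [labels.index(m) for m in subset]
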