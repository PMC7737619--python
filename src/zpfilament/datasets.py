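"""Published input data for the egg-coat digest stoichiometry analysis.

Masses (Da) of the subunit fragments released by protease digestion of
unfertilized fish egg coats, and the cross-linked peak lists measured by
TOF-MS after DSS treatment of the two size-exclusion fractions (F1 and
F2). The ZI-1,2 subunit is cleaved into its two polymerization-module
halves (point masses); the ZI-3 digestion product is heterogeneously
glycosylated and carries a glycoform mass *window* rather than a point
mass.

These numbers are analysis inputs, not fitted values.
"""

from __future__ import annotations

from .xlms import MassComponent, PeakList

# Fragment masses of the two halves of the ZI-1,2 polymerization module.
ZI12_HALF_ZPN_DA = 17846.13
ZI12_HALF_ZPC_DA = 18706.26

# Glycoform window of the ZI-3 digestion product (both halves, glycosylated).
ZI3_WINDOW_DA = (36559.54, 39801.56)

#: "half ZI-1,2" without distinguishing which half: the envelope interval
#: spanned by the two half-module masses, so that k halves occupy
#: [k x lighter, k x heavier]. Used because the measured complexes do not
#: reveal which half participates.
ZI12_HALF_ENVELOPE = MassComponent(
    "ZI-1,2 half", ZI12_HALF_ZPN_DA, ZI12_HALF_ZPC_DA, max_count=4
)

ZI3_COMPONENT = MassComponent("ZI-3", *ZI3_WINDOW_DA, max_count=4)

#: Default component set for the digest stoichiometry solver.
DIGEST_COMPONENTS = (ZI12_HALF_ENVELOPE, ZI3_COMPONENT)

#: Exact components of the F2 heterotrimer (both halves distinguished).
F2_TRIMER_COMPONENTS = (
    MassComponent("ZP-N half", ZI12_HALF_ZPN_DA, ZI12_HALF_ZPN_DA, max_count=4),
    MassComponent("ZP-C half", ZI12_HALF_ZPC_DA, ZI12_HALF_ZPC_DA, max_count=4),
    MassComponent("ZI-3", *ZI3_WINDOW_DA, max_count=4),
)

#: Cross-linked F1 peaks as printed, ascending. The 768038.12 entry is
#: reproduced verbatim although it is inconsistent with its published
#: interpretation (two ZI-3 copies, expected ~73-80 kDa) and is almost
#: certainly a typographical artifact; the solver reports it as having no
#: feasible composition rather than silently correcting it.
F1_PEAKS_DA = (
    55605.79,
    96658.72,
    114825.53,
    133329.12,
    152398.32,
    768038.12,
)

#: The single cross-linked F2 peak (the heterotrimer).
F2_PEAK_DA = 74029.0


def f1_peaklist() -> PeakList:
    return PeakList(masses_da=list(F1_PEAKS_DA), source="F1")


def crosslinked_peaklist() -> PeakList:
    """All printed cross-linked peaks (F1 and F2) in one list."""
    return PeakList(
        masses_da=[*F1_PEAKS_DA, F2_PEAK_DA], source="F1+F2"
    )
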