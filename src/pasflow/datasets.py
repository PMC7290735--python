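"""Published summary numbers from the murine hepatectomy reference study.

The reference study profiled 271 intracellular signaling pathways in mouse
liver after normal (68%, nHx) and extended (86%, eHx) hepatectomy at 1, 8,
16, 32 and 48 h, against sham-operated baselines.  Its full expression data
are archived externally and are not needed here; what this module ships are
the study's *printed* summary numbers, used as inputs to the package's
aggregation and filtering routines (e.g. arithmetic-consistency checks of
the reported pathway counts, or re-filtering the reported strongly
inversely regulated pathways).
"""

from __future__ import annotations

from .compare import RegulationCall, TimepointSummary

N_PATHWAYS = 271
TIME_POINTS = (1, 8, 16, 32, 48)

# Per-time-point counts of arm-specific (unique) activated / silenced
# pathways reported by the reference study, keyed (arm, direction).
UNIQUE_PATHWAY_COUNTS: dict[tuple[str, str], dict[int, int]] = {
    ("nHx", "activated"): {1: 1, 8: 5, 16: 5, 32: 43, 48: 14},
    ("eHx", "activated"): {1: 15, 8: 23, 16: 19, 32: 11, 48: 2},
    ("nHx", "silenced"): {1: 13, 8: 15, 16: 11, 32: 13, 48: 1},
    ("eHx", "silenced"): {1: 2, 8: 4, 16: 6, 32: 15, 48: 3},
}

# At 1 h post surgery: activated pathways in either arm and how many of
# those were common to both arms.
ACTIVATED_AT_1H = 102
COMMON_ACTIVATED_AT_1H = 86

# The strongly inversely regulated pathways: name, time point, the arm the
# printed PAS belongs to, and the printed PAS value.  The study reported 33
# inversely regulated pathways in total, of which these reached the 0.1
# activation-magnitude criterion.
STRONG_INVERSE_PAS: tuple[tuple[str, int, str, float], ...] = (
    ("ATM Pathway (G2_M Checkpoint Arrest)", 1, "nHx", -0.115072046),
    ("CD40 Pathway (Cytokine Expression)", 1, "nHx", -0.106856601),
    ("Circadian Main Pathway", 1, "nHx", 0.119250412),
    ("Hedgehog Main Pathway", 32, "nHx", 0.261337874),
    ("BRCA1 Main Pathway", 32, "nHx", 0.292340978),
    ("ATM Pathway (G2_M Checkpoint Arrest)", 48, "nHx", -0.651298809),
    ("Cytokine Main Pathway", 1, "eHx", 0.110941123),
    ("ErbB Family Main Pathway", 1, "eHx", 0.124348982),
    ("Mitochondrial Apoptosis Pathway", 8, "eHx", 0.181980954),
    ("IL10 Pathway", 16, "eHx", 0.109013662),
    ("Hedgehog Main Pathway", 16, "eHx", -0.141280757),
    ("ATM Pathway (G2_M Checkpoint Arrest)", 48, "eHx", 0.282117965),
    ("cAMP Pathway (Cytokine Production)", 48, "eHx", 0.140344644),
    ("p53 Signaling (Negative) Main Pathway", 48, "eHx", 0.110310831),
)

N_INVERSE_TOTAL = 33


def reference_timepoint_summaries() -> list[TimepointSummary]:
    """The study's per-time-point summaries rebuilt from its printed counts."""
    out = []
    for t in TIME_POINTS:
        counts = {
            f"unique_{arm}_{direction}": UNIQUE_PATHWAY_COUNTS[(arm, direction)][t]
            for arm in ("nHx", "eHx")
            for direction in ("activated", "silenced")
        }
        out.append(TimepointSummary.from_counts(t, N_PATHWAYS, **counts))
    return out


def reference_inverse_calls() -> list[RegulationCall]:
    """Regulation calls for the study's inversely regulated pathways.

    The strongly regulated entries carry the printed per-arm PAS; the
    opposite arm, whose value was not printed, is given an opposite-signed
    placeholder of small magnitude (0.01), which does not affect the
    per-arm-magnitude criterion.  The remaining inverse pathways (printed
    values below the 0.1 criterion were not itemised) are represented by
    synthetic sub-threshold calls so the full set of 33 is present.
    """
    calls = []
    for i, (name, time_h, arm, pas) in enumerate(STRONG_INVERSE_PAS):
        other = -0.01 if pas > 0 else 0.01
        pn, pe = (pas, other) if arm == "nHx" else (other, pas)
        calls.append(RegulationCall(
            pathway_id=f"{name} @{time_h}h",
            time_h=time_h,
            pas_nHx=pn,
            pas_eHx=pe,
            status_nHx="activated" if pn > 0 else "silenced",
            status_eHx="activated" if pe > 0 else "silenced",
            category="inverse",
            strong_inverse=max(abs(pn), abs(pe)) >= 0.1,
        ))
    for j in range(N_INVERSE_TOTAL - len(STRONG_INVERSE_PAS)):
        sign = 1 if j % 2 == 0 else -1
        calls.append(RegulationCall(
            pathway_id=f"sub-threshold inverse pathway {j + 1} (synthetic)",
            time_h=1,
            pas_nHx=sign * 0.05,
            pas_eHx=-sign * 0.05,
            status_nHx="activated" if sign > 0 else "silenced",
            status_eHx="silenced" if sign > 0 else "activated",
            category="inverse",
            strong_inverse=False,
        ))
    return calls
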