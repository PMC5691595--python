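"""Small bundled reference inputs for worked examples.

The admetSAR-predicted absorption and CYP-inhibition profiles below are
the published calls for the five lead flavonoids of *Vernonia
anthelmintica (L.)*, the Uyghur herb screened for melanogenic
(anti-vitiligo) activity. They exercise the scoring surface end to end:
with the default accuracy weights the expected scores are

    Isorhamnetin       1.92963575
    Kaempferide        1.92963575   (identical calls, tied)
    Isoliquiritigenin  1.92766477
    Apigenin           1.76820103
    Liquiritigenin     1.72194393
"""

from __future__ import annotations

from .admet_screen import AdmetRecord


def reference_lead_admet() -> list[AdmetRecord]:
    """Published admetSAR calls for the five lead compounds (see module docs)."""
    rows = {
        "Isorhamnetin": (0.9783, 0.8866, (0.9218, 0.7560, -0.6993, 0.8648, 0.7348)),
        "Kaempferide": (0.9783, 0.8866, (0.9218, 0.7560, -0.6993, 0.8648, 0.7348)),
        "Isoliquiritigenin": (0.9894, 0.8867, (0.935, 0.8949, -0.9231, 0.8994, 0.7959)),
        "Apigenin": (0.9887, 0.8541, (0.9222, 0.7746, -0.9231, 0.7043, 0.9580)),
        "Liquiritigenin": (0.9915, 0.7142, (0.8739, 0.9352, -0.8850, 0.8456, 0.5207)),
    }
    isoforms = ("CYP1A2", "CYP2C9", "CYP2D6", "CYP2C19", "CYP3A4")
    return [
        AdmetRecord(name, hia, caco2, dict(zip(isoforms, cyps)))
        for name, (hia, caco2, cyps) in rows.items()
    ]


#: Expected scores for the records above under the default weights.
REFERENCE_LEAD_SCORES = {
    "Isorhamnetin": 1.92963575,
    "Kaempferide": 1.92963575,
    "Isoliquiritigenin": 1.92766477,
    "Apigenin": 1.76820103,
    "Liquiritigenin": 1.72194393,
}
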