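"""Score and rank the five reference lead flavonoids by the CYP-inhibition score.

The input is the bundled admetSAR-style table of signed probabilities for
five flavonoids; the score weights each signed CYP-inhibition call by the
published accuracy of that isoform's classifier, so a high score means
broad, confidently predicted CYP inhibition (favourable for the oral-route
screen).
"""

from herbnetpharm import absorption_filter, cyp_score, rank_compounds
from herbnetpharm.data import reference_lead_admet

records = reference_lead_admet()
kept = absorption_filter(records)
print(f"{len(kept)}/{len(records)} compounds pass the HIA & Caco-2 absorption gate")

for lead in rank_compounds(kept, top_n=5):
    print(f"  rank {lead.rank}: {lead.compound_id:<18s} score = {lead.score:.8f}")
# The two methyl-flavonoids share identical calls and tie at the top;
# the tie is broken alphabetically by compound id.
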