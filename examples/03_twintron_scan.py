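"""Scan external introns for nested group III introns (twintrons).

Two twintrons are planted in a synthetic genome: a 5' insertion-site motif
and a group III 3' motif inside the external introns of psbC intron 1 and
psbE intron 2.  The scan first matches each external intron against the
reference set (non-homologous introns are called NH), then counts 3' motifs
outside the terminal window and 5' motifs far enough upstream to fit an
internal intron of at least 73 nt.  Cells print as the standard glyphs:
Y[n5,n3], Y*, N, NH, or — for sites without an intron.
"""

from plastocompare.synthetic_data import (SynthSpec, TwintronPlant,
                                          generate_plastome,
                                          generate_reference_set)
from plastocompare.twintron import build_twintron_table, table_to_glyphs

spec = SynthSpec(seed=8, genome_id="demo", n_pcg=12,
                 twintron_plants=(TwintronPlant("psbC", 1, 10, 100),
                                  TwintronPlant("psbE", 2, 5, 150)))
plastome, truth = generate_plastome(spec)
refs = generate_reference_set(spec, truth)
cfg = spec.twintron_config()

sites = [c.site for c in truth.twintron_calls] + [("atpE", 1)]
table = build_twintron_table([("demo", plastome)], sites, refs, cfg)
print(table_to_glyphs(table).to_string())
# Y[1,1] at both planted sites: one 5' insertion site and one internal
# 3' motif each; — for atpE, which carries no intron at the queried site.
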