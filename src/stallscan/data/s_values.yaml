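# Wobble selective constraints for the tRNA adaptation index.
# One value per anticodon:codon pairing class; 1 - s is the efficiency
# weight of the pairing. Watson-Crick pairings carry no penalty; the
# remaining values are the widely used defaults of the original tAI
# formulation (optimized on S. cerevisiae).
watson_crick: 0.0
g_u: 0.41      # anticodon G34 reading codon-ending U
i_c: 0.28      # inosine (gene-encoded A34) reading codon-ending C
i_a: 0.9999    # inosine reading codon-ending A
u_g: 0.68      # anticodon U34 reading codon-ending G
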