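# Fitness components whose raw values are expected to be NEGATIVELY
# related to population fitness.  Effect sizes for these traits have
# their sign inverted so that, throughout the analysis, positive values
# always mean "sexual selection was associated with higher fitness".
# Edit this list to extend the convention to new traits.
negatively_related_traits:
  - parasite load
  - mutation load
  - extinction risk
  - extinction rate
  - male mating latency
  - senescence rate
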