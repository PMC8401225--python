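# Marker-list heuristic for NOVA processing-level assignment.  This is a
# transparent, user-editable approximation: any group-4 marker in the
# ingredient list assigns ultra-processed (4); otherwise any group-3 marker
# assigns processed (3); otherwise minimally processed (1).  Culinary
# ingredients (group 2) are omitted from packaged-supply summaries.
group4_markers:
  - flavouring
  - flavourant
  - flavor
  - flavour
  - colourant
  - colorant
  - emulsifier
  - stabiliser
  - stabilizer
  - thickener
  - glucose syrup
  - high fructose corn syrup
  - maltodextrin
  - invert sugar
  - hydrogenated
  - soy protein isolate
  - whey protein isolate
  - aspartame
  - sucralose
  - acesulfame
  - saccharin
  - cyclamate
  - steviol glycosides
  - sorbitol
  - xylitol
  - maltitol
  - erythritol
  - preservative
  - antioxidant
  - monosodium glutamate
  - raising agent
  - anti-caking agent
group3_markers:
  - salt
  - sugar
  - oil
  - vinegar
  - brine
  - syrup
  - butter
  - honey
default_group: 1
category_defaults: {}
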