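# Non-sugar sweetener search-term list: intense sweeteners and polyols with
# ingredient-list synonyms and INS/E additive codes.  Compiled from standard
# additive nomenclature; versioned so a regulator's official list can be
# dropped in verbatim.
version: "1.0"
terms:
  acesulfame:
    class: intense
    synonyms: ["acesulfame", "acesulfame k", "acesulfame potassium",
               "acesulphame", "e950", "ins 950", "950"]
  aspartame:
    class: intense
    synonyms: ["aspartame", "e951", "ins 951", "951"]
  cyclamate:
    class: intense
    synonyms: ["cyclamate", "sodium cyclamate", "calcium cyclamate",
               "cyclamic acid", "e952", "ins 952", "952"]
  saccharin:
    class: intense
    synonyms: ["saccharin", "sodium saccharin", "saccharin sodium",
               "e954", "ins 954", "954"]
  sucralose:
    class: intense
    synonyms: ["sucralose", "e955", "ins 955", "955"]
  alitame:
    class: intense
    synonyms: ["alitame", "e956", "ins 956", "956"]
  thaumatin:
    class: intense
    synonyms: ["thaumatin", "e957", "ins 957", "957"]
  neohesperidine:
    class: intense
    synonyms: ["neohesperidine dc", "neohesperidine dihydrochalcone", "e959",
               "ins 959", "959"]
  steviol_glycosides:
    class: intense
    synonyms: ["steviol glycosides", "steviol glycoside", "stevia extract",
               "stevia", "rebaudioside a", "rebaudioside m", "rebaudioside",
               "e960", "ins 960", "960"]
  neotame:
    class: intense
    synonyms: ["neotame", "e961", "ins 961", "961"]
  aspartame_acesulfame_salt:
    class: intense
    synonyms: ["aspartame-acesulfame salt", "salt of aspartame-acesulfame",
               "e962", "ins 962", "962"]
  advantame:
    class: intense
    synonyms: ["advantame", "e969", "ins 969", "969"]
  sorbitol:
    class: polyol
    synonyms: ["sorbitol", "sorbitol syrup", "e420", "ins 420", "420"]
  mannitol:
    class: polyol
    synonyms: ["mannitol", "e421", "ins 421", "421"]
  isomalt:
    class: polyol
    synonyms: ["isomalt", "e953", "ins 953", "953"]
  maltitol:
    class: polyol
    synonyms: ["maltitol", "maltitol syrup", "e965", "ins 965", "965"]
  lactitol:
    class: polyol
    synonyms: ["lactitol", "e966", "ins 966", "966"]
  xylitol:
    class: polyol
    synonyms: ["xylitol", "e967", "ins 967", "967"]
  erythritol:
    class: polyol
    synonyms: ["erythritol", "e968", "ins 968", "968"]
  polyglycitol:
    class: polyol
    synonyms: ["polyglycitol syrup", "polyglycitol", "e964", "ins 964", "964"]
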