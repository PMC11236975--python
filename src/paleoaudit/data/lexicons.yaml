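# Default vocabulary for metadata completeness auditing.
# Tags are matched case-insensitively; values/terms on word boundaries.
geo_dedicated_tags:
  - geographic location (region and locality)
  - geographic location (country and/or sea)
  - geographic location (latitude)
  - geographic location (longitude)
  - lat_lon
date_dedicated_tags:
  - date
  - collection date
tissue_dedicated_tags:
  - tissue
  - organism part
  - tissue_type
voucher_tags:
  - specimen voucher
  - biological material
  - culture_collection
freetext_tags:
  - description
  - title
  - note
  - sample description
  - sample comment
tissue_terms:
  - bone
  - tooth
  - teeth
  - petrous
  - petrous bone
  - cementum
  - dentine
  - enamel
  - hair
  - skin
  - calculus
  - rib
  - femur
  - cranium
  - skull
  - phalanx
  - vertebra
  - antler
  - horn
  - eggshell
gazetteer_terms:
  - Norfolk
  - United Kingdom
  - Britain
  - Ireland
  - Iberia
  - Spain
  - Portugal
  - France
  - Germany
  - Italy
  - Scandinavia
  - Sweden
  - Denmark
  - Norway
  - Anatolia
  - Turkey
  - Levant
  - Siberia
  - Mongolia
  - China
  - Japan
  - Kazakhstan
  - Egypt
  - Sudan
  - Morocco
  - Peru
  - Mexico
  - Patagonia
  - Alaska
  - Greenland
  - Ukraine
  - Russia
  - Caucasus
  - Urals
  - Altai
date_patterns:
  - '\b\d[\d,]*(?:\.\d+)?\s*(?:cal\.?\s*)?(?:BP|BCE|BC|CE|AD|ka|kyr)\b'
c14_prefixes:
  - OxA
  - Beta
  - Poz
  - KIA
  - Ua
  - AAR
  - Wk
  - GrA
  - GrM
  - UBA
  - PSUAMS
  - UCIAMS
protocol_terms:
  - single-stranded
  - double-stranded
  - ssDNA
  - dsDNA
  - UDG
  - USER
  - uracil
  - half-UDG
  - non-UDG
  - blunt-end
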