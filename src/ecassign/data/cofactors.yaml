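# Known substrate/product pair table (cofactor couples) and the
# ubiquitous single species removed before pairing.  Compounds are
# identified by the builtin canonical structure key (a table used
# with the InChIKey backend must store InChIKeys instead).  The
# water/ammonia row is preserved from the published pair list but
# disabled by default: water and ammonia are not a conserved
# structural couple, so consuming them as a pair is chemically
# unsafe.  Users may append entries; both directions of a couple
# must be listed if both are to be removed.
pairs:
  - class: NAD_REDOX
    substrate: {name: "NAD+", key: "v1-C21H28N7O14P2-0ff6953b227a57e7"}
    product: {name: "NADH", key: "v1-C21H29N7O14P2-2a9afc6490c68ca7"}
  - class: NAD_REDOX
    substrate: {name: "NADH", key: "v1-C21H29N7O14P2-2a9afc6490c68ca7"}
    product: {name: "NAD+", key: "v1-C21H28N7O14P2-0ff6953b227a57e7"}
  - class: NADP_REDOX
    substrate: {name: "NADP+", key: "v1-C21H29N7O17P3-c66da400f9f56a4d"}
    product: {name: "NADPH", key: "v1-C21H30N7O17P3-badd75040e3fa2cc"}
  - class: NADP_REDOX
    substrate: {name: "NADPH", key: "v1-C21H30N7O17P3-badd75040e3fa2cc"}
    product: {name: "NADP+", key: "v1-C21H29N7O17P3-c66da400f9f56a4d"}
  - class: H2O_NH3
    substrate: {name: "H2O", key: "v1-H2O-dff178574be311cf"}
    product: {name: "NH3", key: "v1-H3N-f795f35c74bf606e"}
    enabled: false
  - class: OXOGLUTARATE_SUCCINATE
    substrate: {name: "2-oxoglutarate", key: "v1-C5H6O5-d0048b2cc2ff97a8"}
    product: {name: "succinate", key: "v1-C4H6O4-18441c0ea99c2dbd"}
  - class: GSSG_GSH
    substrate: {name: "glutathione disulfide", key: "v1-C20H32N6O12S2-102c97fb28a4f0d1"}
    product: {name: "glutathione", key: "v1-C10H17N3O6S-edeb600e51ebcc14"}
  - class: O2_H2O2
    substrate: {name: "O2", key: "v1-O2-31c48cd937833bce"}
    product: {name: "H2O2", key: "v1-H2O2-2f7b62373dd0f4c4"}
  - class: FLAVIN_REDOX
    substrate: {name: "flavin (oxidized)", key: "v1-C13H12N4O2-637972e3102682eb"}
    product: {name: "flavin (reduced)", key: "v1-C13H14N4O2-2c4b708a8347035b"}
ubiquitous:
  - {name: "H+", key: "v1-H-cb0f36908d5aab0b"}
  - {name: "H2O", key: "v1-H2O-dff178574be311cf"}
  - {name: "phosphate", key: "v1-H3O4P-cd4677613144ddf1"}
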