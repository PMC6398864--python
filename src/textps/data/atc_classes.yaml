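# NSAID exposure classes by ATC code.
# COX2 = selective cyclo-oxygenase-2 inhibitors, NSNSAID = nonselective NSAIDs.
COX2:
  - M01AH01   # celecoxib
  - M01AH02   # rofecoxib
  - M01AH03   # valdecoxib
  - M01AH04   # parecoxib
  - M01AH05   # etoricoxib
NSNSAID:
  - M01AB01   # indometacin
  - M01AB05   # diclofenac
  - M01AC06   # meloxicam
  - M01AE01   # ibuprofen
  - M01AE02   # naproxen
  - M01AE03   # ketoprofen
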