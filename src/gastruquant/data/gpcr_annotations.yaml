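# Curated TM1-7 / H8 segment annotations for the receptor structures used in
# chimera-compatibility analysis. These residue ranges are curation, not
# computation: they were assembled from standard literature transmembrane
# annotations of bovine rhodopsin and Smoothened and are approximate at the
# helix termini (+-2 residues). Replace with GPCRdb-derived ranges when exact
# segment boundaries matter. `exclude` lists fusion-construct residue ranges
# to drop on parsing.
structures:
  1u19:            # bovine rhodopsin, inactive state
    chain: A
    exclude: []
    segments:
      TM1: [[34, 64]]
      TM2: [[71, 100]]
      TM3: [[106, 139]]
      TM4: [[150, 173]]
      TM5: [[200, 229]]
      TM6: [[241, 276]]
      TM7: [[285, 309]]
      H8:  [[311, 321]]
  3pqr:            # bovine rhodopsin, active (metarhodopsin II)
    chain: A
    exclude: []
    segments:
      TM1: [[34, 64]]
      TM2: [[71, 100]]
      TM3: [[106, 139]]
      TM4: [[150, 173]]
      TM5: [[200, 229]]
      TM6: [[241, 276]]
      TM7: [[285, 309]]
      H8:  [[311, 321]]
  4jkv:            # human Smoothened TMD, inactive; BRIL fusion excluded
    chain: A
    exclude: [[1001, 1106]]
    segments:
      TM1: [[223, 249]]
      TM2: [[255, 282]]
      TM3: [[291, 323]]
      TM4: [[330, 355]]
      TM5: [[371, 398]]
      TM6: [[408, 438]]
      TM7: [[444, 468]]
      H8:  [[470, 481]]
  6d32:            # Xenopus Smoothened, active state
    chain: A
    exclude: []
    segments:
      TM1: [[220, 246]]
      TM2: [[252, 279]]
      TM3: [[288, 320]]
      TM4: [[327, 352]]
      TM5: [[368, 395]]
      TM6: [[405, 435]]
      TM7: [[441, 465]]
      H8:  [[467, 478]]
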