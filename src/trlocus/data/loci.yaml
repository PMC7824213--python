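# Provenance of the three curated TRA/TRD reference loci.
human:
  species: Homo sapiens
  chromosome: "14"
  orientation: FWD
  span_kb: 1000
  borne5: {gene: OR10G3, distance_kb: 51, found: true}
  borne3: {gene: DAD1, distance_kb: 13, found: true}
bovine:
  species: Bos taurus
  locus_id: IMGT000049
  assembly_accession: CM008177.2
  chromosome: "10"
  orientation: REV
  start: 22253137
  end: 25584362
  complement: true
  gaps: 7
  borne5: {gene: OR10G3, distance_kb: 24, found: true}
  borne3: {gene: DAD1, distance_kb: 12, found: true}
sheep:
  species: Ovis aries
  locus_id: IMGT000048
  assembly_accession: CM008478.1
  chromosome: "7"
  orientation: REV
  start: 23556113
  end: 26437716
  complement: true
  gaps: 18
  borne5: {gene: OR10G3, found: false}
  borne3: {gene: DAD1, distance_kb: 12, found: true}
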