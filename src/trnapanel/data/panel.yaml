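# Consensus panel of 10 species for mt-tRNA conservation assessment,
# with each species' GenBank reference-sequence accession.
#
# Note: the published table lists accession NC_002081 for both Hylobates lar
# and Gadus morhua -- almost certainly a typographical duplication in the
# source (NC_002081 is the H. lar mitochondrion). The duplication is
# preserved here as printed rather than silently corrected; users fetching
# sequences should verify the G. morhua accession independently.
panel:
  - species: Homo sapiens
    group: primate
    accession: NC_012920
    reference: true
  - species: Pan troglodytes
    group: primate
    accession: NC_001643
  - species: Pan paniscus
    group: primate
    accession: NC_001644
  - species: Hylobates lar
    group: primate
    accession: NC_002081
  - species: Mus musculus
    group: mammal
    accession: NC_005089
  - species: Rattus norvegicus
    group: mammal
    accession: NC_001665.2
  - species: Bos taurus
    group: mammal
    accession: NC_006853
  - species: Gallus gallus
    group: vertebrate
    accession: NC_001323
  - species: Gadus morhua
    group: vertebrate
    accession: NC_002081
  - species: Drosophila melanogaster
    group: invertebrate
    accession: NC_001709
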