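# Default interaction-analysis rules (version 1.0).
#
# substitutions: array-reported miRNA ids mapped to the canonical ids used by
# the pathway database. Reasons: host_gene (array reports the miRNA host
# gene), isoform_merge (numbered precursor collapsed onto the family id),
# precursor_variant (distinct precursor with an identical mature sequence).
#
# pathway_groups: ordered keyword rules; the first rule whose include keyword
# appears in the lowercased pathway name (and no exclude keyword does) wins.
# Miscellaneous is the implicit fallback and needs no rule. The keyword lists
# are editable defaults reconstructed from the functional-group memberships
# quoted in the published analysis; note "DNA Repair" excludes "signaling" so
# that e.g. an ATM signaling-network pathway lands in Canonical.
substitutions:
  - {reported_id: mir-548-AJ2, substituted_id: hsa-mir-548aj, reason: precursor_variant}
  - {reported_id: mir-548-AZ, substituted_id: hsa-mir-548az, reason: precursor_variant}
  - {reported_id: mir-548-T, substituted_id: hsa-mir-548t, reason: precursor_variant}
  - {reported_id: mir-181-A1-HG, substituted_id: hsa-mir-181a, reason: host_gene}
  - {reported_id: mir-181-B1, substituted_id: hsa-mir-181b, reason: isoform_merge}
  - {reported_id: mir-31-HG, substituted_id: hsa-mir-31, reason: host_gene}
  - {reported_id: mir-100-HG, substituted_id: hsa-mir-100, reason: host_gene}
  - {reported_id: mir-4477-B, substituted_id: hsa-mir-4477b, reason: isoform_merge}

pathway_groups:
  - group: DNA Repair
    include: [dna repair, mismatch repair, base excision, nucleotide excision,
              double-strand break, homologous recombination, atm]
    exclude: [signaling]
  - group: Cell Cycle
    include: [cell cycle, mitotic, mitosis, chromosom, spindle, checkpoint,
              dna replication, proliferation]
  - group: Apoptosis
    include: [apoptot, apoptosis, programmed cell death, caspase, death receptor]
  - group: Motility
    include: [cell projection, motility, migration, adhesion, cytoskelet, actin,
              lamellipod, filopod, locomotion, chemotaxis, wound healing]
  - group: Cancer
    include: [cancer, glioma, carcinoma, tumor, oncogen, melanoma, leukemia, sarcoma]
  - group: Canonical
    include: [signaling, signal transduction, pathway]
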