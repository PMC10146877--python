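# Built-in saturation-library designs over the E. coli 23S rRNA peptidyl
# transferase center / exit tunnel entrance, 1-based 23S numbering.
#
# wt_source flags the provenance of each wild-type base identity:
#   named     -- base identity stated explicitly in the source study
#   reference -- filled from the E. coli 23S reference sequence; NOT asserted
#                by the study. Override via a user config if needed.
#
# The flanking anchor sequences of the sequencing amplicon are not published;
# the anchors below are synthetic fixtures (arbitrary fixed 20-mers) and are
# meant to be replaced with the real amplicon flanks when analyzing real data.
#
# Condition barcodes (forward = R1 prefix, reverse = R2 prefix) are the
# published demultiplexing barcodes of the selection experiment.
barcode_scheme:
  positive:
    forward: ACTGAAGTACTATG
    reverse: CGATATTCATGCTC
  negative:
    forward: TCAGGATGGACCAT
    reverse: TCGACTGGGTGCAA
  unselected:
    forward: TGTATCTAAGTAC
    reverse: CCTACGTAGAGTT

designs:
  - region_id: "2058-2062"
    positions: [2058, 2059, 2060, 2061, 2062]
    wt_bases: AAAGA
    wt_source: [named, named, named, named, named]
    upstream_anchor: GATTACCGTCAGGCAATCGA
    downstream_anchor: CTTGAGCCAATGGTACGTCA
  - region_id: "2447-2451"
    positions: [2447, 2448, 2449, 2450, 2451]
    wt_bases: GAUAA
    wt_source: [reference, named, reference, named, named]
    upstream_anchor: AGCTTGGACGTTCACTAGCA
    downstream_anchor: TGACCTTAGCGATACGGAAC
  - region_id: "2495-2499"
    positions: [2495, 2496, 2497, 2498, 2499]
    wt_bases: GCACC
    wt_source: [named, reference, reference, reference, reference]
    upstream_anchor: CATGGAGTTCAACGTCTAGG
    downstream_anchor: GTCAATCGGACCATAGCTTG
  - region_id: "2500-2504"
    positions: [2500, 2501, 2502, 2503, 2504]
    wt_bases: UCGAU
    wt_source: [named, named, named, named, named]
    upstream_anchor: TTGCAGACCGTATGAGCAAC
    downstream_anchor: ACGGTATCCATGAGTCGTTC
  - region_id: "2503-2507"
    positions: [2503, 2504, 2505, 2506, 2507]
    wt_bases: AUGUC
    wt_source: [named, named, named, reference, named]
    upstream_anchor: CCTAGAGTTCGGATACACGT
    downstream_anchor: GAACTGTCCATAGGCAGTTA
  - region_id: "2583-2588"
    positions: [2583, 2584, 2585, 2586, 2587, 2588]
    wt_bases: GUUUCA
    wt_source: [named, named, named, named, named, reference]
    upstream_anchor: TCGGAATCCTAGCAAGGTAC
    downstream_anchor: CAGTTACGGATCTGAACGTC
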