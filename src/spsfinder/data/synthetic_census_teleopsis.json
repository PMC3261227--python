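{
  "contig_id": "synth_esplC_td",
  "species": "Td-like",
  "length": 45000,
  "gc": 0.40,
  "genes": [
    {"gene_id": "mdelta", "strand": "+", "cds": [[6000, 6900]],
     "utr_boxes": [["Brd", 12], ["GY", 45], ["K", 80]]},
    {"gene_id": "mgamma", "strand": "+", "cds": [[9500, 10400]],
     "utr_boxes": [["Brd", 12], ["GY", 45], ["K", 80]]},
    {"gene_id": "mbeta", "strand": "+", "cds": [[13000, 13900]],
     "utr_boxes": [["GY", 30]]},
    {"gene_id": "malpha", "strand": "+", "cds": [[16500, 17400]],
     "utr_boxes": [["GY", 20], ["K", 60]]},
    {"gene_id": "m2", "strand": "+", "cds": [[20000, 20900]],
     "utr_boxes": [["K", 25]]},
    {"gene_id": "m3", "strand": "+", "cds": [[23500, 24400]],
     "utr_boxes": [["GY", 40]]},
    {"gene_id": "m4", "strand": "+", "cds": [[27000, 27900]],
     "utr_boxes": [["Brd", 15], ["GY", 50], ["GY", 90]]},
    {"gene_id": "m5", "strand": "+", "cds": [[30500, 31400]],
     "utr_boxes": [["Brd", 18], ["K", 55]]},
    {"gene_id": "m6", "strand": "-", "cds": [[34000, 34900]],
     "utr_boxes": []},
    {"gene_id": "m7", "strand": "+", "cds": [[37500, 38400]],
     "utr_boxes": [["Brd", 35]]},
    {"gene_id": "m8", "strand": "+", "cds": [[41000, 41900]],
     "utr_boxes": [["Brd", 10], ["K", 50], ["K", 95]]}
  ],
  "modules": [
    {"name": "mdelta_SPSA", "gene": "mdelta", "upstream_distance": 4970,
     "spacer": 15, "y_upstream": "T", "y_downstream": "C", "aboxes": [-30]},
    {"name": "mgamma_SPSA", "gene": "mgamma", "upstream_distance": 553,
     "spacer": 17, "y_upstream": "T", "y_downstream": "C", "aboxes": [-25]},
    {"name": "CNS1_SPSA", "gene": "mbeta", "upstream_distance": 900,
     "spacer": 17, "y_upstream": "T", "y_downstream": "C", "aboxes": [20]},
    {"name": "mbeta_SPS", "gene": "mbeta", "upstream_distance": 150,
     "spacer": 17, "y_upstream": "C", "y_downstream": "C", "aboxes": []},
    {"name": "malpha_SPS", "gene": "malpha", "upstream_distance": 200,
     "spacer": 17, "y_upstream": "C", "y_downstream": "C", "aboxes": []},
    {"name": "m2_SPSA", "gene": "m2", "upstream_distance": 420,
     "spacer": 17, "y_upstream": "C", "y_downstream": "C", "aboxes": [-18]},
    {"name": "CNS2_SPS", "gene": "m3", "upstream_distance": 210,
     "spacer": 17, "y_upstream": "T", "y_downstream": "C", "aboxes": []},
    {"name": "m4_SPS", "gene": "m4", "upstream_distance": 180,
     "spacer": 17, "y_upstream": "T", "y_downstream": "C", "aboxes": []},
    {"name": "m5_SPSA", "gene": "m5", "upstream_distance": 260,
     "spacer": 17, "y_upstream": "C", "y_downstream": "C", "aboxes": [-22]},
    {"name": "m7_SPSA", "gene": "m7", "upstream_distance": 469,
     "spacer": 17, "y_upstream": "T", "y_downstream": "C", "aboxes": [-232]},
    {"name": "m8_SPSA", "gene": "m8", "upstream_distance": 338,
     "spacer": 17, "y_upstream": "T", "y_downstream": "C", "aboxes": [-20, 25]}
  ]
}
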