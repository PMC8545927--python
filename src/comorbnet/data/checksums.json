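{
  "mirna_aliases.tsv": "ff05028548dda7b32a5d555e0cff4462ba2d400fb98f43c8280a794562283cb2",
  "table1_dm_counts.tsv": "b3c35080a748b16063f710f4d7ec2bcd7498566b49f6714089a06c9dced0efe2",
  "table2_backbone_centralities.tsv": "3ae1a826ab30d47e6119e397f7990c00e8ca159e12fc1ce2a5c1d65fdaf6fd8c",
  "table3_pathways.gmt": "45bdddb540ba991e7a5fc47164b8ee6901507ca261c00373c157ac5afd8b1a86",
  "table4_counts.tsv": "ee0b63df913da70bd9623990351f5c1a8232164e103645e7f0237264272acdbc",
  "table4_mirna_edges.tsv": "ac5aca8bae86352ab85894125837b9582c9dc3e55f0e91099ff10b6af426c6e8"
}
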