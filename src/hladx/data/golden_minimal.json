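{
  "hml": {
    "created": "2024-11-20T00:00:00Z",
    "extras": [],
    "message_id": "NUTTT-IHW9224-001",
    "reporting_center": "NUTTT",
    "samples": [
      {
        "extras": [],
        "id": "IHW9224",
        "properties": {
          "lab-ref": "NUTTT",
          "patient-ref": "IHW9224",
          "tc-ref": "NLUT1"
        },
        "typings": [
          {
            "allele_assignment": {
              "allele_db": "IPD-IMGT/HLA",
              "allele_version": "3.57.0",
              "date": "2024-11-20",
              "glstring": "HLA-A*01:01:01:01+HLA-A*02:01:01:01"
            },
            "consensus_sequence": null,
            "extras": [],
            "gene_family": "HLA",
            "typing_method": null
          },
          {
            "allele_assignment": {
              "allele_db": "IPD-IMGT/HLA",
              "allele_version": "3.57.0",
              "date": "2024-11-20",
              "glstring": "HLA-B*07:02:01:01+HLA-B*08:01:01:01"
            },
            "consensus_sequence": null,
            "extras": [],
            "gene_family": "HLA",
            "typing_method": null
          },
          {
            "allele_assignment": {
              "allele_db": "IPD-IMGT/HLA",
              "allele_version": "3.57.0",
              "date": "2024-11-20",
              "glstring": "HLA-DRB1*14:01:01/HLA-DRB1*14:54:01+HLA-DRB1*15:01:01:01"
            },
            "consensus_sequence": null,
            "extras": [],
            "gene_family": "HLA",
            "typing_method": null
          }
        ]
      }
    ],
    "version": "1.0.1"
  }
}
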