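<?xml version="1.0" encoding="UTF-8"?>
<hml version="1.0.1" created="2024-11-20T00:00:00Z">
  <hmlid extension="NUTTT-IHW9224-001" />
  <reporting-center reporting-center-id="NUTTT" />
  <sample id="IHW9224">
    <property name="lab-ref" value="NUTTT" />
    <property name="patient-ref" value="IHW9224" />
    <property name="tc-ref" value="NLUT1" />
    <typing gene-family="HLA">
      <allele-assignment allele-db="IPD-IMGT/HLA" allele-version="3.57.0" date="2024-11-20">
        <glstring>HLA-A*01:01:01:01+HLA-A*02:01:01:01</glstring>
      </allele-assignment>
    </typing>
    <typing gene-family="HLA">
      <allele-assignment allele-db="IPD-IMGT/HLA" allele-version="3.57.0" date="2024-11-20">
        <glstring>HLA-B*07:02:01:01+HLA-B*08:01:01:01</glstring>
      </allele-assignment>
    </typing>
    <typing gene-family="HLA">
      <allele-assignment allele-db="IPD-IMGT/HLA" allele-version="3.57.0" date="2024-11-20">
        <glstring>HLA-DRB1*14:01:01/HLA-DRB1*14:54:01+HLA-DRB1*15:01:01:01</glstring>
      </allele-assignment>
    </typing>
  </sample>
</hml>
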