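description: 'Frozen construct fixtures: prefactors calibrated against each construct''s
  target isochronal V0.5 (and published kinetics for WT/A548V).'
constructs:
  WT:
    params:
      A1_0: 0.05262741621765768
      B1_0: 0.01232351263617096
      A2_0: 0.005565729110781761
      B2_0: 0.00031322734625738476
    cell: {}
    tail_voltage: -70.0
    target_v05: -23.1
    provenance: published
  D540A:
    params:
      A1_0: 0.05262741621765768
      B1_0: 0.01232351263617096
      A2_0: 0.004772940908649038
      B2_0: 0.0003652545867891521
    cell: {}
    tail_voltage: -70.0
    target_v05: -20.5
    provenance: synthetic
  R541A:
    params:
      A1_0: 0.05262741621765768
      B1_0: 0.01232351263617096
      A2_0: 0.006610430672623844
      B2_0: 0.000263725413016951
    cell: {}
    tail_voltage: -70.0
    target_v05: -26.0
    provenance: synthetic
  Y542A:
    params:
      A1_0: 0.05262741621765768
      B1_0: 0.01232351263617096
      A2_0: 0.004500285829924415
      B2_0: 0.00038738396298417454
    cell: {}
    tail_voltage: -70.0
    target_v05: -19.5
    provenance: synthetic
  S543A:
    params:
      A1_0: 0.05262741621765768
      B1_0: 0.01232351263617096
      A2_0: 0.025652552193087468
      B2_0: 6.795965353604926e-05
    cell: {}
    tail_voltage: -120.0
    target_v05: -48.0
    provenance: published
  E544A:
    params:
      A1_0: 0.05262741621765768
      B1_0: 0.01232351263617096
      A2_0: 0.0062313681321401445
      B2_0: 0.00027976818611724364
    cell: {}
    tail_voltage: -70.0
    target_v05: -25.0
    provenance: synthetic
  Y545A:
    params:
      A1_0: 0.05262741621765768
      B1_0: 0.01232351263617096
      A2_0: 0.007232032997503764
      B2_0: 0.0002410578823353519
    cell: {}
    tail_voltage: -70.0
    target_v05: -27.5
    provenance: synthetic
  G546A:
    params:
      A1_0: 0.05262741621765768
      B1_0: 0.01232351263617096
      A2_0: 0.07166258620241193
      B2_0: 2.4327039418219732e-05
    cell: {}
    tail_voltage: -120.0
    target_v05: -63.8
    provenance: published
  A547V:
    params:
      A1_0: 0.05262741621765768
      B1_0: 0.01232351263617096
      A2_0: 0.0050629000594864535
      B2_0: 0.00034433596138069475
    cell: {}
    tail_voltage: -70.0
    target_v05: -21.5
    provenance: synthetic
  A548V:
    params:
      A1_0: 0.03694866222383088
      B1_0: 0.0029992563589647495
      A2_0: 0.013935135178557528
      B2_0: 1.879418094950262e-05
    cell: {}
    tail_voltage: -120.0
    target_v05: -56.8
    provenance: published
  V549A:
    params:
      A1_0: 0.05262741621765768
      B1_0: 0.01232351263617096
      A2_0: 0.00424385578710785
      B2_0: 0.00041079118773395336
    cell: {}
    tail_voltage: -70.0
    target_v05: -18.5
    provenance: synthetic
  L550A:
    params:
      A1_0: 0.05262741621765768
      B1_0: 0.01232351263617096
      A2_0: 0.017576449878879657
      B2_0: 9.918604561052388e-05
    cell: {}
    tail_voltage: -120.0
    target_v05: -42.0
    provenance: published
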