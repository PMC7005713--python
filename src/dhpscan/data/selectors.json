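{
  "_comment": "Phosphorylatable-His author residue numbers per kinase, recorded from the deposited PDB entries. Used only in coordinate mode (local structure files); manifest mode needs none of them. null = not recorded here; supply via a user config when running coordinate mode on that entry.",
  "proteins": {
    "HK853": {"his_residue": 260, "organism": "Thermotoga maritima"},
    "WalK": {"his_residue": 386, "organism": "Lactobacillus plantarum"},
    "VicK": {"his_residue": 471, "organism": "Streptococcus mutans"},
    "EnvZ-HAMP-DHp": {"his_residue": 243, "organism": "Escherichia coli"},
    "EnvZ-DHp": {"his_residue": 243, "organism": "Escherichia coli"},
    "EnvZ-chim": {"his_residue": 243, "organism": "Escherichia coli (chimeric)"},
    "EnvZ-HAMP-Af1503": {"his_residue": null, "organism": "chimera (Af1503 HAMP / EnvZ DHp-CA)"},
    "CpxA": {"his_residue": 248, "organism": "Escherichia coli"},
    "PhoR-DHp": {"his_residue": 259, "organism": "Mycobacterium tuberculosis"},
    "ERS1-DHp": {"his_residue": 353, "organism": "Arabidopsis thaliana"},
    "RetS-DHp-CA": {"his_residue": 424, "organism": "Pseudomonas aeruginosa"}
  }
}
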