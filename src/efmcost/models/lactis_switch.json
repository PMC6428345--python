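{
  "constraints": [
    {
      "bound": 1.0,
      "id": "total_enzyme",
      "weights": {
        "biomass": 1.0,
        "homolactic": 1.0,
        "mixed_acid": 1.0
      }
    },
    {
      "bound": 0.4,
      "id": "uptake",
      "weights": {
        "homolactic": 2.8,
        "mixed_acid": 0.4
      }
    }
  ],
  "format_version": "1.0",
  "metabolites": [
    {
      "external": true,
      "id": "glucose_ext"
    },
    {
      "external": false,
      "id": "atp"
    }
  ],
  "reactions": [
    {
      "id": "mixed_acid",
      "kcat": 2.0,
      "objective": false,
      "saturation": {
        "Ki": 0.15,
        "Km": {
          "glucose_ext": 0.04
        },
        "inhibitor_id": "atp",
        "kind": "mm_product_inhibition"
      },
      "stoichiometry": {
        "atp": 2.0,
        "glucose_ext": -1.0
      }
    },
    {
      "id": "homolactic",
      "kcat": 8.0,
      "objective": false,
      "saturation": {
        "Ki": 10.0,
        "Km": {
          "glucose_ext": 1.0
        },
        "inhibitor_id": "atp",
        "kind": "mm_product_inhibition"
      },
      "stoichiometry": {
        "atp": 1.0,
        "glucose_ext": -1.0
      }
    },
    {
      "id": "biomass",
      "kcat": 14.0,
      "objective": true,
      "saturation": {
        "Km": {
          "atp": 0.5
        },
        "kind": "michaelis_menten"
      },
      "stoichiometry": {
        "atp": -1.0
      }
    }
  ]
}
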