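{
  "constraints": [
    {
      "bound": 1.0,
      "id": "cytosol",
      "weights": {
        "overflow": 1.0,
        "respiration": 1.0
      }
    },
    {
      "bound": 0.3,
      "id": "membrane",
      "weights": {
        "transport": 1.0
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
      "id": "intermediate"
    },
    {
      "external": false,
      "id": "precursor"
    },
    {
      "external": true,
      "id": "acetate_ext"
    }
  ],
  "reactions": [
    {
      "id": "transport",
      "kcat": 10.0,
      "objective": false,
      "saturation": {
        "Km": {
          "glucose_ext": 1.0
        },
        "kind": "michaelis_menten"
      },
      "stoichiometry": {
        "glucose_ext": -1.0,
        "intermediate": 1.0
      }
    },
    {
      "id": "respiration",
      "kcat": 1.0,
      "objective": false,
      "saturation": {
        "Km": {
          "intermediate": 1.0
        },
        "kind": "michaelis_menten"
      },
      "stoichiometry": {
        "intermediate": -1.0,
        "precursor": 1.0
      }
    },
    {
      "id": "overflow",
      "kcat": 3.0,
      "objective": false,
      "saturation": {
        "Km": {
          "intermediate": 1.0
        },
        "kind": "michaelis_menten"
      },
      "stoichiometry": {
        "acetate_ext": 1.0,
        "intermediate": -2.0,
        "precursor": 1.0
      }
    },
    {
      "id": "biomass",
      "kcat": 10.0,
      "objective": true,
      "saturation": {
        "Km": {
          "precursor": 1.0
        },
        "kind": "michaelis_menten"
      },
      "stoichiometry": {
        "precursor": -1.0
      }
    }
  ]
}
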