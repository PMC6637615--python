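{
 "meta": {
  "schema_version": "1"
 },
 "entities": [
  {
   "id": "E1",
   "kind": "protein",
   "name": "E1",
   "product_of": "gE1",
   "ubiquitous": false
  },
  {
   "id": "E2",
   "kind": "protein",
   "name": "E2",
   "product_of": "gE2",
   "ubiquitous": false
  },
  {
   "id": "E3",
   "kind": "protein",
   "name": "E3",
   "product_of": "gE3",
   "ubiquitous": false
  },
  {
   "id": "E4",
   "kind": "protein",
   "name": "E4",
   "product_of": "gE4",
   "ubiquitous": false
  },
  {
   "id": "E5",
   "kind": "protein",
   "name": "E5",
   "product_of": "gE5",
   "ubiquitous": false
  },
  {
   "id": "M0",
   "kind": "metabolite",
   "name": "M0",
   "ubiquitous": false
  },
  {
   "id": "M1",
   "kind": "metabolite",
   "name": "M1",
   "ubiquitous": false
  },
  {
   "id": "M2",
   "kind": "metabolite",
   "name": "M2",
   "ubiquitous": false
  },
  {
   "id": "M3",
   "kind": "metabolite",
   "name": "M3",
   "ubiquitous": false
  },
  {
   "id": "M4",
   "kind": "metabolite",
   "name": "M4",
   "ubiquitous": false
  },
  {
   "id": "M5",
   "kind": "metabolite",
   "name": "M5",
   "ubiquitous": false
  },
  {
   "id": "TF0",
   "kind": "protein",
   "name": "TF0",
   "product_of": "gTF0",
   "ubiquitous": false
  },
  {
   "id": "TF0_dim",
   "kind": "complex",
   "name": "TF0 dimer",
   "components": [
    [
     "TF0",
     2
    ]
   ],
   "ubiquitous": false
  },
  {
   "id": "TF1",
   "kind": "protein",
   "name": "TF1",
   "product_of": "gTF1",
   "ubiquitous": false
  },
  {
   "id": "TF2",
   "kind": "protein",
   "name": "TF2",
   "product_of": "gTF2",
   "ubiquitous": false
  },
  {
   "id": "WATER",
   "kind": "metabolite",
   "name": "water",
   "ubiquitous": true
  },
  {
   "id": "gE1",
   "kind": "gene",
   "name": "gE1",
   "ubiquitous": false
  },
  {
   "id": "gE2",
   "kind": "gene",
   "name": "gE2",
   "ubiquitous": false
  },
  {
   "id": "gE3",
   "kind": "gene",
   "name": "gE3",
   "ubiquitous": false
  },
  {
   "id": "gE4",
   "kind": "gene",
   "name": "gE4",
   "ubiquitous": false
  },
  {
   "id": "gE5",
   "kind": "gene",
   "name": "gE5",
   "ubiquitous": false
  },
  {
   "id": "gTF0",
   "kind": "gene",
   "name": "gTF0",
   "ubiquitous": false
  },
  {
   "id": "gTF1",
   "kind": "gene",
   "name": "gTF1",
   "ubiquitous": false
  },
  {
   "id": "gTF2",
   "kind": "gene",
   "name": "gTF2",
   "ubiquitous": false
  }
 ],
 "reactions": [
  {
   "id": "R1",
   "reactants": [
    "M0"
   ],
   "products": [
    "M1"
   ],
   "direction": "left-to-right",
   "enzymes": [
    "E1"
   ],
   "is_transport": false,
   "is_protein_binding": false
  },
  {
   "id": "R2",
   "reactants": [
    "M1",
    "WATER"
   ],
   "products": [
    "M2"
   ],
   "direction": "left-to-right",
   "enzymes": [
    "E2"
   ],
   "is_transport": false,
   "is_protein_binding": false
  },
  {
   "id": "R3",
   "reactants": [
    "M2"
   ],
   "products": [
    "M3"
   ],
   "direction": "left-to-right",
   "enzymes": [
    "E3"
   ],
   "is_transport": false,
   "is_protein_binding": false
  },
  {
   "id": "R4",
   "reactants": [
    "M3"
   ],
   "products": [
    "M4"
   ],
   "direction": "left-to-right",
   "enzymes": [
    "E4"
   ],
   "is_transport": false,
   "is_protein_binding": false
  },
  {
   "id": "R5",
   "reactants": [
    "M5"
   ],
   "products": [
    "M0"
   ],
   "direction": "left-to-right",
   "enzymes": [
    "E5"
   ],
   "is_transport": false,
   "is_protein_binding": false
  }
 ],
 "regulations": [
  {
   "id": "reg1",
   "regulator": "TF0",
   "regulatee": "gTF1",
   "mode": "transcriptional",
   "sign": "-"
  },
  {
   "id": "reg2",
   "regulator": "TF0",
   "regulatee": "gE5",
   "mode": "transcriptional",
   "sign": "+"
  },
  {
   "id": "reg3",
   "regulator": "TF1",
   "regulatee": "gE2",
   "mode": "transcriptional",
   "sign": "+"
  },
  {
   "id": "reg4",
   "regulator": "TF1",
   "regulatee": "gE3",
   "mode": "transcriptional",
   "sign": "-"
  },
  {
   "id": "reg5",
   "regulator": "TF2",
   "regulatee": "gE4",
   "mode": "transcriptional",
   "sign": "+"
  },
  {
   "id": "reg6",
   "regulator": "M3",
   "regulatee": "E1",
   "mode": "enzyme-modulation",
   "sign": "-"
  },
  {
   "id": "reg7",
   "regulator": "M5",
   "regulatee": "E1",
   "mode": "cofactor",
   "sign": "+"
  }
 ],
 "transcription_units": [
  {
   "id": "tu1",
   "genes": [
    "gE2",
    "gE3"
   ]
  }
 ]
}
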