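[
 {
  "id": "ptr:Per",
  "kind": "inequality",
  "weight": 5,
  "desired": 20.0,
  "direction": "gt",
  "compute": {
   "type": "ptr",
   "species": "p"
  }
 },
 {
  "id": "ptr:Cry1",
  "kind": "numeric",
  "weight": 3,
  "desired": 2.1,
  "direction": null,
  "compute": {
   "type": "ptr",
   "species": "c1"
  }
 },
 {
  "id": "ptr:Cry2",
  "kind": "numeric",
  "weight": 3,
  "desired": 2.2,
  "direction": null,
  "compute": {
   "type": "ptr",
   "species": "c2"
  }
 },
 {
  "id": "ptr:Ror",
  "kind": "numeric",
  "weight": 3,
  "desired": 4.1,
  "direction": null,
  "compute": {
   "type": "ptr",
   "species": "ror"
  }
 },
 {
  "id": "ptr:Rev-erba",
  "kind": "inequality",
  "weight": 5,
  "desired": 10.0,
  "direction": "gt",
  "compute": {
   "type": "ptr",
   "species": "rev"
  }
 },
 {
  "id": "ptr:Bmal1",
  "kind": "inequality",
  "weight": 5,
  "desired": 10.0,
  "direction": "gt",
  "compute": {
   "type": "ptr",
   "species": "b"
  }
 },
 {
  "id": "ptr:PER",
  "kind": "inequality",
  "weight": 5,
  "desired": 20.0,
  "direction": "gt",
  "compute": {
   "type": "ptr",
   "species": "P"
  }
 },
 {
  "id": "ptr:CRY1",
  "kind": "numeric",
  "weight": 3,
  "desired": 3.7,
  "direction": null,
  "compute": {
   "type": "ptr",
   "species": "C1"
  }
 },
 {
  "id": "ptr:CRY2",
  "kind": "numeric",
  "weight": 3,
  "desired": 1.8,
  "direction": null,
  "compute": {
   "type": "ptr",
   "species": "C2"
  }
 },
 {
  "id": "ptr:ROR",
  "kind": "inequality",
  "weight": 5,
  "desired": 5.0,
  "direction": "lt",
  "compute": {
   "type": "ptr",
   "species": "ROR"
  }
 },
 {
  "id": "ptr:REV",
  "kind": "inequality",
  "weight": 5,
  "desired": 5.0,
  "direction": "lt",
  "compute": {
   "type": "ptr",
   "species": "REV"
  }
 },
 {
  "id": "ptr:BMAL1",
  "kind": "numeric",
  "weight": 3,
  "desired": 2.9,
  "direction": null,
  "compute": {
   "type": "ptr",
   "species": "B"
  }
 },
 {
  "id": "ra:PER/PER+CRY1+CRY2",
  "kind": "numeric",
  "weight": 10,
  "desired": 0.11,
  "direction": null,
  "compute": {
   "type": "ra",
   "num": [
    "P"
   ],
   "den": [
    "P",
    "C1",
    "C2"
   ]
  }
 },
 {
  "id": "ra:CRY1/PER+CRY1+CRY2",
  "kind": "numeric",
  "weight": 10,
  "desired": 0.56,
  "direction": null,
  "compute": {
   "type": "ra",
   "num": [
    "C1"
   ],
   "den": [
    "P",
    "C1",
    "C2"
   ]
  }
 },
 {
  "id": "ra:CRY2/PER+CRY1+CRY2",
  "kind": "numeric",
  "weight": 10,
  "desired": 0.34,
  "direction": null,
  "compute": {
   "type": "ra",
   "num": [
    "C2"
   ],
   "den": [
    "P",
    "C1",
    "C2"
   ]
  }
 },
 {
  "id": "ra:BMAL1/CRY1",
  "kind": "numeric",
  "weight": 3,
  "desired": 0.19,
  "direction": null,
  "compute": {
   "type": "ra",
   "num": [
    "B"
   ],
   "den": [
    "C1"
   ]
  }
 },
 {
  "id": "ra:ROR/REV",
  "kind": "numeric",
  "weight": 3,
  "desired": 1.02,
  "direction": null,
  "compute": {
   "type": "ra",
   "num": [
    "ROR"
   ],
   "den": [
    "REV"
   ]
  }
 },
 {
  "id": "ra:Ror/Rev-erba",
  "kind": "numeric",
  "weight": 3,
  "desired": 0.78,
  "direction": null,
  "compute": {
   "type": "ra",
   "num": [
    "ror"
   ],
   "den": [
    "rev"
   ]
  }
 },
 {
  "id": "ra:Bmal1/Per",
  "kind": "numeric",
  "weight": 3,
  "desired": 0.78,
  "direction": null,
  "compute": {
   "type": "ra",
   "num": [
    "b"
   ],
   "den": [
    "p"
   ]
  }
 },
 {
  "id": "ra:Bmal1/Ror",
  "kind": "numeric",
  "weight": 3,
  "desired": 1.01,
  "direction": null,
  "compute": {
   "type": "ra",
   "num": [
    "b"
   ],
   "den": [
    "ror"
   ]
  }
 },
 {
  "id": "ra:Bmal1/Rev-erba",
  "kind": "numeric",
  "weight": 3,
  "desired": 0.78,
  "direction": null,
  "compute": {
   "type": "ra",
   "num": [
    "b"
   ],
   "den": [
    "rev"
   ]
  }
 },
 {
  "id": "ra:Per/Ror",
  "kind": "numeric",
  "weight": 3,
  "desired": 1.29,
  "direction": null,
  "compute": {
   "type": "ra",
   "num": [
    "p"
   ],
   "den": [
    "ror"
   ]
  }
 },
 {
  "id": "ra:Per/Rev-erba",
  "kind": "numeric",
  "weight": 3,
  "desired": 0.99,
  "direction": null,
  "compute": {
   "type": "ra",
   "num": [
    "p"
   ],
   "den": [
    "rev"
   ]
  }
 },
 {
  "id": "pd:Per->PER",
  "kind": "numeric",
  "weight": 10,
  "desired": 75.0,
  "direction": null,
  "compute": {
   "type": "pd",
   "a": "p",
   "b": "P"
  }
 },
 {
  "id": "pd:Cry1->CRY1",
  "kind": "numeric",
  "weight": 5,
  "desired": 75.0,
  "direction": null,
  "compute": {
   "type": "pd",
   "a": "c1",
   "b": "C1"
  }
 },
 {
  "id": "pd:Cry2->CRY2",
  "kind": "numeric",
  "weight": 5,
  "desired": 67.0,
  "direction": null,
  "compute": {
   "type": "pd",
   "a": "c2",
   "b": "C2"
  }
 },
 {
  "id": "pd:Bmal1->BMAL1",
  "kind": "numeric",
  "weight": 5,
  "desired": 0.0,
  "direction": null,
  "compute": {
   "type": "pd",
   "a": "b",
   "b": "B"
  }
 },
 {
  "id": "pd:Ror->ROR",
  "kind": "numeric",
  "weight": 5,
  "desired": 67.0,
  "direction": null,
  "compute": {
   "type": "pd",
   "a": "ror",
   "b": "ROR"
  }
 },
 {
  "id": "pd:Rev-erba->REV",
  "kind": "numeric",
  "weight": 5,
  "desired": 58.0,
  "direction": null,
  "compute": {
   "type": "pd",
   "a": "rev",
   "b": "REV"
  }
 },
 {
  "id": "pd:Bmal1->Per",
  "kind": "numeric",
  "weight": 15,
  "desired": 54.0,
  "direction": null,
  "compute": {
   "type": "pd",
   "a": "b",
   "b": "p"
  }
 },
 {
  "id": "pd:Bmal1->Cry1",
  "kind": "numeric",
  "weight": 15,
  "desired": 25.0,
  "direction": null,
  "compute": {
   "type": "pd",
   "a": "b",
   "b": "c1"
  }
 },
 {
  "id": "pd:Bmal1->Ror",
  "kind": "numeric",
  "weight": 5,
  "desired": 29.0,
  "direction": null,
  "compute": {
   "type": "pd",
   "a": "b",
   "b": "ror"
  }
 },
 {
  "id": "pd:Bmal1->Rev-erba",
  "kind": "numeric",
  "weight": 5,
  "desired": 67.0,
  "direction": null,
  "compute": {
   "type": "pd",
   "a": "b",
   "b": "rev"
  }
 },
 {
  "id": "pd:Rev-erba->PER",
  "kind": "numeric",
  "weight": 50,
  "desired": 50.0,
  "direction": null,
  "compute": {
   "type": "pd",
   "a": "rev",
   "b": "P"
  }
 },
 {
  "id": "pd:Rev-erba->Ror",
  "kind": "numeric",
  "weight": 5,
  "desired": 79.0,
  "direction": null,
  "compute": {
   "type": "pd",
   "a": "rev",
   "b": "ror"
  }
 },
 {
  "id": "pd:Per->Cry2",
  "kind": "numeric",
  "weight": 5,
  "desired": 0.0,
  "direction": null,
  "compute": {
   "type": "pd",
   "a": "p",
   "b": "c2"
  }
 },
 {
  "id": "pd:CRY1->CRY1N",
  "kind": "numeric",
  "weight": 5,
  "desired": 0.0,
  "direction": null,
  "compute": {
   "type": "pd",
   "a": "C1",
   "b": "C1N"
  }
 },
 {
  "id": "pd:CRY2->CRY2N",
  "kind": "numeric",
  "weight": 5,
  "desired": 0.0,
  "direction": null,
  "compute": {
   "type": "pd",
   "a": "C2",
   "b": "C2N"
  }
 },
 {
  "id": "ko:Cry1_sensitivity",
  "kind": "inequality",
  "weight": 50,
  "desired": 0.0,
  "direction": "lt",
  "compute": {
   "type": "ko_sensitivity",
   "gene": "Cry1"
  }
 },
 {
  "id": "ko:Cry2_sensitivity",
  "kind": "inequality",
  "weight": 50,
  "desired": 0.0,
  "direction": "gt",
  "compute": {
   "type": "ko_sensitivity",
   "gene": "Cry2"
  }
 },
 {
  "id": "ko:Cry1_period",
  "kind": "inequality",
  "weight": 100,
  "desired": 0.95,
  "direction": "lt",
  "compute": {
   "type": "ko_period",
   "gene": "Cry1"
  }
 },
 {
  "id": "ko:Cry2_period",
  "kind": "inequality",
  "weight": 100,
  "desired": 1.15,
  "direction": "gt",
  "compute": {
   "type": "ko_period",
   "gene": "Cry2"
  }
 }
]
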