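{
  "patients": [
    {
      "patient_id": "p1",
      "condition": "chest pain",
      "urgency": 2,
      "required_resources": {"ecg": 1},
      "location": "north",
      "feature_tokens": [],
      "numeric_features": [1.0, 0.0]
    },
    {
      "patient_id": "p2",
      "condition": "ankle sprain",
      "urgency": 4,
      "required_resources": {},
      "location": "south",
      "feature_tokens": [],
      "numeric_features": [0.0, 1.0]
    },
    {
      "patient_id": "p3",
      "condition": "fever cough",
      "urgency": 3,
      "required_resources": {"lab": 2},
      "location": "east",
      "feature_tokens": [],
      "numeric_features": null
    }
  ],
  "providers": [
    {
      "provider_id": "r1",
      "specialties": ["cardiology"],
      "capacity": 2,
      "available_resources": {"ecg": 1, "lab": 1},
      "location": "north",
      "services": ["ecg", "chest"],
      "numeric_features": [1.0, 0.0]
    },
    {
      "provider_id": "r2",
      "specialties": ["orthopedics"],
      "capacity": 1,
      "available_resources": {},
      "location": "south",
      "services": ["sprain"],
      "numeric_features": [0.0, 1.0]
    },
    {
      "provider_id": "r3",
      "specialties": ["general", "medicine"],
      "capacity": 3,
      "available_resources": {"lab": 2},
      "location": "east",
      "services": ["lab", "fever"],
      "numeric_features": [1.0, 1.0]
    }
  ]
}
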