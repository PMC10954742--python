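{
  "msfd_order": ["EMED", "CMED", "ADRIA", "WMED"],
  "countries": {
    "GR": {"name": "Greece", "msfd": ["EMED", "CMED"], "default": "EMED"},
    "TR": {"name": "Turkey", "msfd": ["EMED"], "default": "EMED"},
    "SY": {"name": "Syria", "msfd": ["EMED"], "default": "EMED"},
    "CY": {"name": "Cyprus", "msfd": ["EMED"], "default": "EMED"},
    "LB": {"name": "Lebanon", "msfd": ["EMED"], "default": "EMED"},
    "IL": {"name": "Israel", "msfd": ["EMED"], "default": "EMED"},
    "PS": {"name": "Palestine Authority", "msfd": ["EMED"], "default": "EMED"},
    "EG": {"name": "Egypt", "msfd": ["EMED"], "default": "EMED"},
    "LY": {"name": "Libya", "msfd": ["EMED", "CMED"], "default": "EMED"},
    "MT": {"name": "Malta", "msfd": ["CMED"], "default": "CMED"},
    "IT": {"name": "Italy", "msfd": ["ADRIA", "CMED", "WMED"], "default": "CMED"},
    "TN": {"name": "Tunisia", "msfd": ["CMED", "WMED"], "default": "CMED"},
    "AL": {"name": "Albania", "msfd": ["ADRIA"], "default": "ADRIA"},
    "ME": {"name": "Montenegro", "msfd": ["ADRIA"], "default": "ADRIA"},
    "HR": {"name": "Croatia", "msfd": ["ADRIA"], "default": "ADRIA"},
    "ES": {"name": "Spain", "msfd": ["WMED"], "default": "WMED"},
    "DZ": {"name": "Algeria", "msfd": ["WMED"], "default": "WMED"}
  }
}
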