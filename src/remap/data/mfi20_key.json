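{
  "version": "mfi-20/1.0",
  "description": "Multidimensional Fatigue Inventory item-to-domain map and the reverse-keyed (positively phrased) item set. Domain score = sum of its four items after reverse-keying (6 - response); range 4-20, higher = worse fatigue.",
  "domains": {
    "general_fatigue": [1, 5, 12, 16],
    "physical_fatigue": [2, 8, 14, 20],
    "reduced_activity": [3, 6, 10, 17],
    "reduced_motivation": [4, 9, 15, 18],
    "mental_fatigue": [7, 11, 13, 19]
  },
  "reverse_keyed": [2, 5, 9, 10, 13, 14, 16, 17, 18, 19]
}
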