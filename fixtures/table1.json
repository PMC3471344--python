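{
 "events": [
  {
   "a": 3,
   "anchor": -1,
   "chromosome": "G"
  },
  {
   "a": 1,
   "anchor": -4,
   "chromosome": "H"
  },
  {
   "a": 1,
   "anchor": 5,
   "chromosome": "G"
  },
  {
   "a": 3,
   "anchor": 4,
   "chromosome": "G"
  },
  {
   "a": 4,
   "anchor": -5,
   "chromosome": "H"
  }
 ],
 "length": 16,
 "offset": 7
}
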