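{
 "schema_version": 1,
 "provenance": "Reference shift/coupling values as printed for HMDB entries in the source study narrative (fucose HMDB00174, ketoleucine HMDB00695).",
 "references": [
  {
   "metabolite_id": "fucose",
   "source": "HMDB00174",
   "h_shifts": [
    {
     "assignment": "b_me",
     "ppm": 1.26
    },
    {
     "assignment": "a_me",
     "ppm": 1.2
    },
    {
     "assignment": "a_h1",
     "ppm": 5.19
    },
    {
     "assignment": "b_h1",
     "ppm": 4.54
    },
    {
     "assignment": "b_h5",
     "ppm": 3.8
    },
    {
     "assignment": "a_h5",
     "ppm": 4.18
    },
    {
     "assignment": "b_h2",
     "ppm": 3.46
    }
   ],
   "c_shifts": [
    {
     "assignment": "b_me",
     "ppm": 18.3
    },
    {
     "assignment": "a_me",
     "ppm": 18.3
    },
    {
     "assignment": "a_h1",
     "ppm": 95.1
    },
    {
     "assignment": "b_h1",
     "ppm": 99.0
    }
   ],
   "couplings": [
    {
     "assignment": [
      "a_me",
      "a_h5"
     ],
     "hz": 6.7
    },
    {
     "assignment": [
      "b_me",
      "b_h5"
     ],
     "hz": 6.6
    },
    {
     "assignment": [
      "a_h1",
      "a_h2"
     ],
     "hz": 3.9
    },
    {
     "assignment": [
      "b_h1",
      "b_h2"
     ],
     "hz": 7.9
    }
   ]
  },
  {
   "metabolite_id": "ketoleucine",
   "source": "HMDB00695",
   "h_shifts": [
    {
     "assignment": "me",
     "ppm": 0.93
    },
    {
     "assignment": "ch",
     "ppm": 2.09
    },
    {
     "assignment": "ch2",
     "ppm": 2.6
    }
   ],
   "c_shifts": [
    {
     "assignment": "me",
     "ppm": 24.4
    },
    {
     "assignment": "ch",
     "ppm": 26.7
    },
    {
     "assignment": "ch2",
     "ppm": 50.8
    }
   ],
   "couplings": [
    {
     "assignment": [
      "me",
      "ch"
     ],
     "hz": 6.7
    },
    {
     "assignment": [
      "ch",
      "ch2"
     ],
     "hz": 7.0
    }
   ]
  }
 ]
}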