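{
 "description": "frozen toy-fixture displacements (verified build)",
 "samples": [
  {
   "freq_index": 0,
   "node": 0,
   "re": 1.6021864269686224e-08,
   "im": -1.4079573905019966e-09
  },
  {
   "freq_index": 0,
   "node": 10,
   "re": 6.362418338266674e-08,
   "im": -9.583759731165457e-09
  },
  {
   "freq_index": 0,
   "node": 25,
   "re": -3.1752407170456714e-07,
   "im": 1.1004097573545017e-07
  },
  {
   "freq_index": 0,
   "node": 40,
   "re": 9.37182988422256e-07,
   "im": -7.419278100342703e-09
  },
  {
   "freq_index": 0,
   "node": 50,
   "re": -9.119063039981659e-07,
   "im": 3.413715786489769e-08
  },
  {
   "freq_index": 1,
   "node": 0,
   "re": 6.687540422196276e-09,
   "im": -4.703344517401405e-09
  },
  {
   "freq_index": 1,
   "node": 10,
   "re": -2.66869481616916e-07,
   "im": -4.175066278559325e-08
  },
  {
   "freq_index": 1,
   "node": 25,
   "re": 1.4528081069814264e-06,
   "im": 6.529672422619711e-08
  },
  {
   "freq_index": 1,
   "node": 40,
   "re": -2.9473876559451702e-08,
   "im": -2.9846781597874606e-09
  },
  {
   "freq_index": 1,
   "node": 50,
   "re": 3.1736299362838454e-13,
   "im": 3.612861438718737e-14
  }
 ]
}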