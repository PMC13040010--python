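source	canonical
difficulty concentrating	diminished ability to concentrate
trouble sleeping	insomnia
low mood	depressed mood
feeling down	depressed mood
tiredness	fatigue
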