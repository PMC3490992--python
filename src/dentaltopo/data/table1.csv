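order_name,family,genus,species,collection,number,n_upper_teeth,n_lower_teeth,upper_opcr,lower_opcr,t,d,a,w
Carnivora,Canidae,Alopex,lagopus,FMNH,1345,3,3,154.25,96.75,3.22,8.71,22.21,56.20
Carnivora,Canidae,Canis,mesomelas,NMV,C32235,3,3,147.25,124.38,5.90,7.54,38.05,64.82
Carnivora,Canidae,Canis,aureus,ZMB,52447,3,3,172.62,132.88,3.37,10.16,19.73,70.00
Carnivora,Canidae,Vulpes,vulpes,NMV,C25076,3,3,153.38,111.38,4.44,9.75,24.49,65.48
Carnivora,Canidae,Vulpes,vulpes,NMV,C25077,3,3,150.12,113.62,4.10,8.43,25.93,66.88
Carnivora,Felidae,Acinonyx,jubatus,FMNH,U31,2,1,52.62,36.50,4.80,11.41,23.39,108.60
Carnivora,Felidae,Neofelis,nebulosa,NMV,R11997,2,1,42.62,18.38,4.71,14.04,18.55,97.48
Carnivora,Herpestidae,Herpestes,ichneumon,ZMB,83028,3,2,144.25,101.12,2.87,6.04,29.46,41.70
Carnivora,Herpestidae,Mungos,mungo,NMV,R1555,3,2,120.25,80.62,2.70,4.46,31.16,32.81
Carnivora,Herpestidae,Suricata,suricatta,NMV,R2454,3,2,162.62,64.12,1.12,1.24,42.18,38.63
Carnivora,Herpestidae,Suricata,suricatta,NMV,R2486,3,2,143.12,77.25,0.76,1.67,24.43,38.57
Carnivora,Hyaenidae,Crocuta,crocuta,FMNH,30.196,2,1,76.12,55.88,4.77,18.92,14.76,123.00
Carnivora,Mustelidae,Mustela,putorius,NMV,C22360,2,2,73.38,42.88,0.93,3.58,14.56,31.02
Carnivora,Mustelidae,Mustela,putorius,NMV,C32788,2,2,76.38,37.25,1.30,2.96,23.72,32.84
Carnivora,Mustelidae,Mustela,frenata,NMV,C11225,2,2,75.25,41.38,1.17,2.61,24.11,25.76
Carnivora,Mustelidae,Mustela,frenata,NMV,C31304,2,2,60.50,38.88,1.23,2.41,27.03,18.32
Carnivora,Mustelidae,Mustela,lutreola,ZMB,94308,2,2,119.25,71.25,0.92,3.31,16.36,34.70
Carnivora,Mustelidae,Vormela,peregusna,SMNH,A91 5107,2,2,113.25,56.75,0.94,2.94,19.05,28.90
Carnivora,Viverridae,Genetta,genetta,SMNH,A58 042,3,2,143.88,139.50,2.21,3.60,40.45,34.90
Carnivora,Viverridae,Viverra,zibetha,NMV,C1845,3,2,129.62,83.88,2.83,5.36,27.82,37.51
Dasyuromorphia,Dasyuridae,Dasycercus,cristicauda,NMV,C5364,4,4,251.88,188.25,1.34,1.80,36.59,22.65
Dasyuromorphia,Dasyuridae,Dasycercus,cristicauda,NMV,C5356,4,4,238.38,180.50,1.42,1.55,42.40,22.83
Dasyuromorphia,Dasyuridae,Dasyurus,geoffroii,NMV,C31515,4,4,212.12,170.62,2.03,3.67,28.93,38.99
Dasyuromorphia,Dasyuridae,Dasyurus,geoffroii,NMV,C31560,4,4,218.50,158.62,2.04,4.70,23.45,42.60
Dasyuromorphia,Dasyuridae,Dasyurus,maculatus,NMV,C6108,4,4,240.62,165.25,3.77,4.91,37.49,43.68
Dasyuromorphia,Dasyuridae,Dasyurus,maculatus,NMV,C29669,4,4,224.50,152.50,2.52,5.54,24.45,49.65
Dasyuromorphia,Dasyuridae,Dasyurus,hallucatus,MUZ,4735,4,4,214.88,162.25,2.43,3.30,36.38,31.62
Dasyuromorphia,Dasyuridae,Dasyurus,viverrinus,MUZ,5737,4,4,214.88,168.75,5.98,9.26,32.86,39.72
Dasyuromorphia,Dasyuridae,Phascogale,tapoatafa,NMV,C27059,4,4,292.88,204.88,1.84,2.27,38.99,28.73
Dasyuromorphia,Dasyuridae,Phascogale,tapoatafa,NMV,C34784,4,4,301.62,190.25,1.37,2.20,31.91,24.13
Dasyuromorphia,Dasyuridae,Sarcophilus,harrisii,NMV,C6232,4,4,169.75,114.62,4.83,11.01,23.69,83.50
Dasyuromorphia,Dasyuridae,Sarcophilus,harrisii,NMV,C6233,4,4,162.88,116.00,5.21,11.92,23.61,87.68
Dasyuromorphia,Thylacinidae,Thylacinus,cynocephalus,NMV,C5748,4,4,133.38,98.75,6.01,11.44,27.73,86.76
Dasyuromorphia,Thylacinidae,Thylacinus,cynocephalus,NMV,C5747,4,4,144.38,102.62,8.79,12.72,34.65,108.77
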