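# config_hash=fixture:three_block_mini seed=7
day_id,block_index,trial_in_block,rule,color_morph,shape_morph,action,reward,latent_color_percept,latent_shape_percept,latent_color_sign,latent_shape_sign
0,0,1,R3,0.0,0.0,UR,0,-1.0416484951276583,1.3727156216477034,-1,-1
0,0,2,R3,30.0,170.0,LL,0,-1.515248060261138,-0.8564261469996675,-1,-1
0,0,3,R3,50.0,100.0,UL,0,-0.8661352959097179,-1.0978679689942776,1,1
0,0,4,R3,0.0,0.0,LR,0,2.9138373759763088,1.192856363232508,-1,-1
0,0,5,R3,130.0,0.0,LL,0,2.3125529189017273,2.3586169361782368,1,-1
0,0,6,R3,100.0,150.0,LL,0,-0.47986772997069016,-2.840681488174126,1,-1
0,1,1,R2,170.0,170.0,LR,0,1.633583367284496,1.91804172145768,-1,-1
0,1,2,R2,0.0,170.0,LL,1,-2.9787671561477502,3.086283773558973,-1,-1
0,1,3,R2,170.0,170.0,LR,0,2.474543143403702,1.5010427133311115,-1,-1
0,1,4,R2,50.0,100.0,UR,0,-2.027114968282505,0.6210172587002689,-1,1
0,1,5,R2,170.0,30.0,UR,0,2.2048234873345534,-2.023771039764286,-1,-1
0,1,6,R2,100.0,70.0,UR,1,-0.7008294612313235,-1.200744359822572,1,1
0,2,1,R3,0.0,170.0,UR,0,-2.4240398770889513,-3.1243463343304514,-1,-1
0,2,2,R3,30.0,30.0,LL,0,-1.6510722104617184,-1.8669980197705005,-1,-1
0,2,3,R3,30.0,130.0,UL,1,-2.69559571040549,1.2206326455406034,-1,1
0,2,4,R3,30.0,170.0,UL,1,-3.085261309866553,1.1046672417045391,-1,-1
0,2,5,R3,130.0,70.0,UL,0,2.2636480164417883,-1.760514154228126,1,1
0,2,6,R3,150.0,0.0,UR,0,1.2786449314434094,-2.2173645575959293,-1,-1
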