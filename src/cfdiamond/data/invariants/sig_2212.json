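{"signature":[2,2,1,2],"reduced":[["m",0],["m",1],["m",2],["m",3],["m",4],["u1",5],["u2",5],["m",6],["m",7],["m",8],["m",9],["m",10],["m",11],["m",12]],"provenance":"numeric-interpolation+swap","max_degree":2,"polys":[[[1,1,[1]],[-3,1,[0,7]],[3,1,[0,8]],[-3,1,[2,3]]],[[1,1,[0]],[-1,2,[3]],[-3,2,[0,5]],[1,1,[3,5]],[1,2,[3,6]],[-1,2,[4,5]],[-1,1,[4,6]]],[[1,1,[2]],[1,1,[7]],[-1,1,[8]],[-1,1,[2,5]],[-2,1,[2,6]]],[[1,1,[3]],[-1,1,[4]],[-1,1,[3,5]],[-1,2,[3,6]],[1,2,[4,5]],[1,1,[4,6]]],[[2,1,[0,7]],[-2,1,[0,8]],[-1,1,[1,6]],[1,1,[2,4]]],[[2,1,[0,7]],[-2,1,[0,8]],[-1,1,[1,5]],[3,1,[2,3]],[-2,1,[2,4]]],[[1,1,[0,2]],[-1,1,[0,7]],[1,1,[0,8]],[-1,1,[2,3]]],[[1,1,[0,5]],[-1,1,[0,6]],[-1,1,[3,5]],[-1,2,[3,6]],[1,2,[4,5]],[1,1,[4,6]]]],"checksum":"8bf9fa94f2eb9db506328bd8b051d4f5253e94b5b3107ba7962d69d731fbf954"}
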